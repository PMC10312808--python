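"""Synthetic study generator.

Produces a full fake cohort with a known generative link so every
downstream stage (thresholds, QC, screening, group splits, fMRI
associations) can be exercised and its effect recovery tested offline:

* per-hemisphere 180-parcel surface-area tables with lognormal
  between-subject variation,
* subject-specific excitatory and attention widths tied (affine-decreasing,
  clipped) to parietal and frontal normalized surface area,
* per-condition true thresholds from the normalization model plus
  multiplicative lognormal noise,
* trial-level Psi staircase behavior, with a minority of inattentive
  observers who lapse into guessing late in each staircase ("rising"
  staircases),
* block-design ROI timecourses whose response amplitude increases with
  frontal surface-area share.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .anatomy import FRONTAL_REGION, PARIETAL_REGION, ParcelTable
from . import model as nm
from .fmri import BlockTimecourse
from .psychometrics import (
    DEFAULT_GAMMA,
    DEFAULT_LAPSE,
    WeibullParams,
    StaircaseRecord,
    run_staircase,
)

__all__ = [
    "CohortConfig",
    "SubjectTruth",
    "StudyBundle",
    "cond_label",
    "gap_label",
    "generate_parcels",
    "link_parameters",
    "generate_true_thresholds",
    "simulate_trials",
    "simulate_fmri",
    "simulate_study",
    "records_to_frame",
    "frame_to_records",
]

EXCIT_RANGE = (3.0, 4.5)
ATTN_RANGE = (3.0, 7.0)
GAP_SIZES_DEG = (0.5, 1.0, 1.5, 2.5, 4.5)
SURROUND_OUTER_DEG = 7.75
EXP2_TARGET_DIAM_DEG = 1.0


def cond_label(size_deg: float, contrast: float) -> str:
    return f"size{size_deg:g}_con{contrast:g}"


def gap_label(gap_deg: float) -> str:
    return f"gap{gap_deg:g}"


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for the synthetic cohort."""

    seed: int
    n_subjects: int = 62
    n_parcels_per_hemi: int = 180
    parcel_share_sd: float = 0.25  # lognormal sd of parcel shares
    total_sa_mean_mm2: float = 9.0e4
    total_sa_sd: float = 0.08  # lognormal sd of hemisphere totals
    excit_slope: float = 3.0  # d sigma_e per z of parietal share (decreasing)
    attn_slope: float = 8.0  # d sigma_a per z of frontal share (decreasing)
    threshold_noise_sd: float = 0.04  # lognormal sd of threshold noise
    bad_fraction: float = 11 / 73  # inattentive ("rising staircase") observers
    beta_sd: float = 0.12  # lognormal sd of observer slopes around 3
    n_runs: int = 4
    fmri_amp_base: float = 1.2  # % signal change for high contrast
    fmri_amp_slope: float = 0.25  # d amplitude per z of frontal share (increasing)
    fmri_amp_noise_sd: float = 0.10
    fmri_noise_sd: float = 0.04  # additive timecourse noise (% of baseline)
    fmri_n_runs: int = 2
    model_params: nm.ModelParams = nm.DEFAULT_PARAMS
    sizes_deg: tuple[float, ...] = nm.DEFAULT_SIZES_DEG
    contrasts: tuple[float, ...] = nm.DEFAULT_CONTRASTS

    def __post_init__(self) -> None:
        if self.n_subjects < 8:
            raise ValueError("need at least 8 subjects")
        if self.n_parcels_per_hemi < 7:
            raise ValueError("need at least 7 parcels per hemisphere")
        for name in (
            "parcel_share_sd",
            "total_sa_sd",
            "threshold_noise_sd",
            "beta_sd",
            "fmri_amp_noise_sd",
            "fmri_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.bad_fraction < 1:
            raise ValueError("bad_fraction must lie in [0, 1)")
        # linkage must stay within the manipulated parameter ranges by clipping
        if self.excit_slope < 0 or self.attn_slope < 0:
            raise ValueError("linkage slopes must be nonnegative")


@dataclass
class SubjectTruth:
    """Ground-truth generative parameters for one synthetic subject."""

    subject_id: str
    parietal_share: float
    frontal_share: float
    sigma_e: float
    sigma_a: float
    bad_observer: bool
    thresholds_ms: dict[str, float] = field(default_factory=dict)
    hmt_amplitude: float = float("nan")

    def __post_init__(self) -> None:
        if not EXCIT_RANGE[0] <= self.sigma_e <= EXCIT_RANGE[1]:
            raise ValueError("sigma_e outside its manipulated range")
        if not ATTN_RANGE[0] <= self.sigma_a <= ATTN_RANGE[1]:
            raise ValueError("sigma_a outside its manipulated range")


def _parcel_names(n: int) -> list[str]:
    named = ["7AL", "VIP", "LIPd", "IP1", "IP2", "11l"]
    generic = [f"P{i:03d}" for i in range(1, n - len(named) + 1)]
    return named + generic


def _subject_ids(n: int) -> list[str]:
    return [f"sub{i:03d}" for i in range(1, n + 1)]


def generate_parcels(
    cfg: CohortConfig, rng: np.random.Generator
) -> tuple[ParcelTable, pd.DataFrame]:
    """Raw surface-area table plus the true per-subject region shares.

    Parcel shares are lognormal draws renormalized to sum to 1 per
    hemisphere, so typical parcels occupy ~1/n_parcels (~0.56% at 180) of
    the hemisphere; raw values multiply shares by a lognormal hemisphere
    total around 9e4 mm^2.
    """
    names = _parcel_names(cfg.n_parcels_per_hemi)
    subjects = _subject_ids(cfg.n_subjects)
    columns = pd.MultiIndex.from_product([["LH", "RH"], names], names=["hemi", "parcel"])
    values = np.empty((cfg.n_subjects, len(columns)))
    share_rows = []
    for i in range(cfg.n_subjects):
        row = []
        shares_by_hemi = {}
        for hemi in ("LH", "RH"):
            raw = np.exp(rng.normal(0.0, cfg.parcel_share_sd, cfg.n_parcels_per_hemi))
            shares = raw / raw.sum()
            total = cfg.total_sa_mean_mm2 * np.exp(rng.normal(0.0, cfg.total_sa_sd))
            row.append(shares * total)
            shares_by_hemi[hemi] = dict(zip(names, shares))
        values[i] = np.concatenate(row)
        parietal = sum(
            shares_by_hemi[h][p] for h, p in sorted(PARIETAL_REGION.members)
        )
        frontal = sum(shares_by_hemi[h][p] for h, p in sorted(FRONTAL_REGION.members))
        share_rows.append((subjects[i], parietal, frontal))
    table = ParcelTable(pd.DataFrame(values, index=subjects, columns=columns), "raw")
    shares = pd.DataFrame(
        share_rows, columns=["subject_id", "parietal_share", "frontal_share"]
    ).set_index("subject_id")
    return table, shares


def _affine_clip(z: np.ndarray, slope: float, lo: float, hi: float) -> np.ndarray:
    mid = (lo + hi) / 2
    return np.clip(mid - slope * z, lo, hi)


def link_parameters(
    shares: pd.DataFrame, cfg: CohortConfig, rng: np.random.Generator
) -> list[SubjectTruth]:
    """Map region shares to per-subject model widths (affine-decreasing, clipped).

    Shares are z-scored across the cohort; larger parietal share gives a
    narrower excitatory width, larger frontal share a narrower attention
    width.  Zero slopes put every subject at the midpoint.
    """

    def zscore(x: pd.Series) -> np.ndarray:
        sd = x.std(ddof=0)
        if sd == 0:
            return np.zeros(len(x))
        return ((x - x.mean()) / sd).to_numpy()

    z_par = zscore(shares["parietal_share"])
    z_fro = zscore(shares["frontal_share"])
    sigma_e = _affine_clip(z_par, cfg.excit_slope, *EXCIT_RANGE)
    sigma_a = _affine_clip(z_fro, cfg.attn_slope, *ATTN_RANGE)
    n_bad = int(round(cfg.bad_fraction * len(shares)))
    bad_idx = set(rng.choice(len(shares), size=n_bad, replace=False).tolist())
    return [
        SubjectTruth(
            subject_id=str(sid),
            parietal_share=float(shares["parietal_share"].iloc[i]),
            frontal_share=float(shares["frontal_share"].iloc[i]),
            sigma_e=float(sigma_e[i]),
            sigma_a=float(sigma_a[i]),
            bad_observer=i in bad_idx,
        )
        for i, sid in enumerate(shares.index)
    ]


def _exp1_stimuli(cfg: CohortConfig) -> dict[str, nm.StimulusSpec]:
    p = cfg.model_params
    return {
        cond_label(s, c): nm.StimulusSpec(extent=p.au(s), contrast=c)
        for s in cfg.sizes_deg
        for c in cfg.contrasts
    }


def _exp2_stimuli(cfg: CohortConfig) -> dict[str, nm.StimulusSpec]:
    p = cfg.model_params
    stims = {}
    for gap in GAP_SIZES_DEG:
        stims[gap_label(gap)] = nm.StimulusSpec(
            extent=p.au(EXP2_TARGET_DIAM_DEG),
            contrast=0.98,
            surround=nm.SurroundSpec(
                gap=p.au(gap), outer_extent=p.au(SURROUND_OUTER_DEG)
            ),
        )
    stims["no_surround"] = nm.StimulusSpec(
        extent=p.au(EXP2_TARGET_DIAM_DEG), contrast=0.98
    )
    return stims


def generate_true_thresholds(
    truths: Sequence[SubjectTruth],
    cfg: CohortConfig,
    rng: np.random.Generator,
    stimuli: dict[str, nm.StimulusSpec] | None = None,
    spacing: float | None = None,
) -> list[SubjectTruth]:
    """Attach per-condition model thresholds x lognormal subject noise.

    A single spatial grid (sized for the largest stimulus, spacing tied to
    the narrowest admissible excitatory width) is shared across subjects.
    """
    if stimuli is None:
        stimuli = _exp1_stimuli(cfg)
    base = cfg.model_params
    if spacing is None:
        spacing = EXCIT_RANGE[0] / 16.0
    grid = nm.default_grid(base, stimuli.values(), spacing=spacing)
    out = []
    for truth in truths:
        params = replace(base, excit_width=truth.sigma_e, attn_width=truth.sigma_a)
        noise = np.exp(rng.normal(0.0, cfg.threshold_noise_sd, len(stimuli)))
        thresholds = {
            cond: float(nm.predict_stimulus_threshold(stim, params, grid) * eps)
            for (cond, stim), eps in zip(stimuli.items(), noise)
        }
        out.append(replace_truth(truth, thresholds_ms=thresholds))
    return out


def replace_truth(truth: SubjectTruth, **kw) -> SubjectTruth:
    data = {**truth.__dict__, **kw}
    return SubjectTruth(**data)


P80_FACTOR = (-np.log(1 - (0.80 - DEFAULT_GAMMA) / (1 - DEFAULT_GAMMA - DEFAULT_LAPSE)))


def _alpha_for_threshold(threshold_ms: float, beta: float) -> float:
    """Weibull alpha whose 80% point equals ``threshold_ms``."""
    return threshold_ms / P80_FACTOR ** (1.0 / beta)


def simulate_trials(
    truths: Sequence[SubjectTruth],
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> list[StaircaseRecord]:
    """Psi staircases (n_runs per condition) for every subject.

    Good observers respond from their Weibull (lapses included).  Bad
    observers guess (p = 0.5) from a random late trial onward in every
    staircase, producing rising running estimates that the QC ratio rule
    targets.
    """
    records = []
    for truth in truths:
        for cond in sorted(truth.thresholds_ms):
            target = truth.thresholds_ms[cond]
            for run in range(1, cfg.n_runs + 1):
                beta = float(3.0 * np.exp(rng.normal(0.0, cfg.beta_sd)))
                alpha = _alpha_for_threshold(target, beta)
                observer = WeibullParams(alpha, beta)
                response_fn = None
                if truth.bad_observer:
                    t_guess = int(rng.integers(11, 17))

                    def response_fn(i, x, r, _obs=observer, _t=t_guess):
                        if i >= _t:
                            return r.random() < 0.5
                        from .psychometrics import weibull_p_correct

                        return r.random() < weibull_p_correct(x, _obs)

                records.append(
                    run_staircase(
                        observer,
                        rng=rng,
                        condition=cond,
                        subject_id=truth.subject_id,
                        run=run,
                        response_fn=response_fn,
                    )
                )
    return records


def records_to_frame(records: Sequence[StaircaseRecord]) -> pd.DataFrame:
    """Trial TSV layout: subject_id, condition, run, trial, duration_ms,
    correct, running_estimate_ms."""
    rows = []
    for rec in records:
        for i, t in enumerate(rec.trials, start=1):
            rows.append(
                (
                    rec.subject_id,
                    rec.condition,
                    rec.run,
                    i,
                    t.duration_ms,
                    int(t.correct),
                    t.running_estimate_ms,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "run",
            "trial",
            "duration_ms",
            "correct",
            "running_estimate_ms",
        ],
    )


def frame_to_records(frame: pd.DataFrame) -> list[StaircaseRecord]:
    from .psychometrics import Trial

    records = []
    for (sid, cond, run), grp in frame.groupby(
        ["subject_id", "condition", "run"], sort=True
    ):
        grp = grp.sort_values("trial")
        trials = tuple(
            Trial(float(r.duration_ms), bool(r.correct), float(r.running_estimate_ms))
            for r in grp.itertuples()
        )
        records.append(StaircaseRecord(str(cond), trials, str(sid), int(run)))
    return records


# ---------------------------------------------------------------------------
# fMRI simulation
# ---------------------------------------------------------------------------

_BLOCK_LEN_TR = 5
_TR_S = 2.0


def _hrf(t: np.ndarray) -> np.ndarray:
    """Fixed double-gamma-shaped kernel (peak ~6 s, small undershoot)."""
    from scipy.stats import gamma as gamma_dist

    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h


def _block_response_shape() -> np.ndarray:
    """Response of one 10-s block at TR resolution, normalized so the mean
    over the 8-12 s post-onset samples is exactly 1."""
    t = np.arange(0, 32, _TR_S)
    hrf = _hrf(t)
    boxcar = np.zeros_like(t)
    boxcar[:_BLOCK_LEN_TR] = 1.0
    resp = np.convolve(boxcar, hrf)[: t.size]
    readout = resp[4:7].mean()  # samples at +8, +10, +12 s
    return resp / readout


_SHAPE = _block_response_shape()


def _design(n_stim: int = 12) -> tuple[list[int], list[str], int]:
    """Alternating block design: blank, stim, blank, ... (13 blanks)."""
    onsets, conds = [], []
    tr = _BLOCK_LEN_TR  # first blank occupies TRs [0, 5)
    for i in range(n_stim):
        onsets.append(tr)
        conds.append("low" if i % 2 == 0 else "high")
        tr += 2 * _BLOCK_LEN_TR  # stim block + following blank
    n_tr = tr
    return onsets, conds, n_tr


def simulate_fmri(
    truths: Sequence[SubjectTruth],
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> tuple[list[SubjectTruth], list[tuple[str, BlockTimecourse]]]:
    """Block-design ROI timecourses with amplitude tied to frontal share.

    High-contrast amplitude is affine-increasing in the z-scored frontal
    share (x lognormal noise); low contrast responds at half amplitude.
    FD traces are mostly quiet with occasional injected spikes, and a small
    fraction of runs get sub-0.6 hit rates, so both QC rules fire.
    """
    fro = np.array([t.frontal_share for t in truths])
    sd = fro.std() or 1.0
    z = (fro - fro.mean()) / sd
    onsets, conds, n_tr = _design()
    baseline = 1000.0
    out_truths = []
    runs = []
    for i, truth in enumerate(truths):
        amp = cfg.fmri_amp_base * (1.0 + cfg.fmri_amp_slope * z[i])
        amp = max(amp, 0.05) * float(np.exp(rng.normal(0.0, cfg.fmri_amp_noise_sd)))
        out_truths.append(replace_truth(truth, hmt_amplitude=amp))
        for _run in range(cfg.fmri_n_runs):
            signal = np.full(n_tr, baseline)
            for onset, cond in zip(onsets, conds):
                a = amp if cond == "high" else 0.5 * amp
                seg = _SHAPE[: n_tr - onset]
                signal[onset : onset + seg.size] += baseline * (a / 100.0) * seg
            signal = signal + baseline * (cfg.fmri_noise_sd / 100.0) * rng.standard_normal(n_tr)
            fd = rng.uniform(0.02, 0.25, n_tr)
            if rng.random() < 0.25:  # motion spike hits ~a quarter of runs
                fd[int(rng.integers(0, n_tr))] = float(rng.uniform(1.0, 2.5))
            hit = float(rng.uniform(0.75, 1.0))
            if rng.random() < 0.05:
                hit = float(rng.uniform(0.30, 0.55))
            runs.append(
                (
                    truth.subject_id,
                    BlockTimecourse(
                        samples=signal,
                        onsets=tuple(onsets),
                        conditions=tuple(conds),
                        fd_mm=fd,
                        hit_rate=hit,
                        tr_s=_TR_S,
                        block_len_tr=_BLOCK_LEN_TR,
                    ),
                )
            )
    return out_truths, runs


def fmri_runs_to_frames(
    runs: Sequence[tuple[str, BlockTimecourse]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TSV layouts: (timecourse rows, block/design+hit-rate rows)."""
    tc_rows, block_rows = [], []
    run_counter: dict[str, int] = {}
    for sid, tc in runs:
        run_idx = run_counter.get(sid, 0) + 1
        run_counter[sid] = run_idx
        for t in range(tc.samples.size):
            tc_rows.append((sid, run_idx, t, tc.samples[t], tc.fd_mm[t]))
        for onset, cond in zip(tc.onsets, tc.conditions):
            block_rows.append((sid, run_idx, onset, cond, tc.hit_rate))
    tc_frame = pd.DataFrame(
        tc_rows, columns=["subject_id", "run", "tr_index", "signal", "fd_mm"]
    )
    block_frame = pd.DataFrame(
        block_rows, columns=["subject_id", "run", "onset_index", "condition", "hit_rate"]
    )
    return tc_frame, block_frame


def frames_to_fmri_runs(
    tc_frame: pd.DataFrame, block_frame: pd.DataFrame
) -> list[tuple[str, BlockTimecourse]]:
    runs = []
    for (sid, run), grp in tc_frame.groupby(["subject_id", "run"], sort=True):
        grp = grp.sort_values("tr_index")
        blocks = block_frame[
            (block_frame["subject_id"] == sid) & (block_frame["run"] == run)
        ].sort_values("onset_index")
        runs.append(
            (
                str(sid),
                BlockTimecourse(
                    samples=grp["signal"].to_numpy(),
                    onsets=tuple(int(v) for v in blocks["onset_index"]),
                    conditions=tuple(str(v) for v in blocks["condition"]),
                    fd_mm=grp["fd_mm"].to_numpy(),
                    hit_rate=float(blocks["hit_rate"].iloc[0]),
                    tr_s=_TR_S,
                    block_len_tr=_BLOCK_LEN_TR,
                ),
            )
        )
    return runs


# ---------------------------------------------------------------------------
# Whole-study bundles
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    config: CohortConfig
    parcels: ParcelTable
    truths: list[SubjectTruth]
    records: list[StaircaseRecord]
    fmri_runs: list[tuple[str, BlockTimecourse]]

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": t.subject_id,
                "parietal_share": t.parietal_share,
                "frontal_share": t.frontal_share,
                "sigma_e": t.sigma_e,
                "sigma_a": t.sigma_a,
                "bad_observer": t.bad_observer,
                "hmt_amplitude": t.hmt_amplitude,
                **{f"thr_{k}": v for k, v in sorted(t.thresholds_ms.items())},
            }
            for t in self.truths
        ]
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.parcels.to_tsv(outdir / "parcels.tsv")
        records_to_frame(self.records).to_csv(
            outdir / "trials.tsv", sep="\t", index=False
        )
        if self.fmri_runs:
            tc, blocks = fmri_runs_to_frames(self.fmri_runs)
            tc.to_csv(outdir / "timecourses.tsv", sep="\t", index=False)
            blocks.to_csv(outdir / "blocks.tsv", sep="\t", index=False)
        truth = self.truth_frame()
        (outdir / "truth.json").write_text(
            json.dumps(truth.to_dict(orient="records"), indent=1, sort_keys=True)
        )


PRESETS = ("exp1", "exp2", "exp4", "null")


def preset_config(preset: str, seed: int, n: int | None = None) -> CohortConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    kw: dict = {"seed": seed}
    if preset == "exp2":
        kw["n_subjects"] = n if n is not None else 29
        # surround stimuli are strongly suppressed; rescale so simulated gap
        # thresholds stay in the range where the QC ratio rule is reliable
        kw["model_params"] = replace(nm.DEFAULT_PARAMS, scale_k=95.0)
    elif preset == "exp4":
        kw["n_subjects"] = n if n is not None else 30
    elif n is not None:
        kw["n_subjects"] = n
    if preset == "null":
        kw.update(excit_slope=0.0, attn_slope=0.0, fmri_amp_slope=0.0)
    return CohortConfig(**kw)


def simulate_study(cfg: CohortConfig, preset: str = "exp1") -> StudyBundle:
    """Generate the full study for a preset, deterministically from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    parcels, shares = generate_parcels(cfg, rng)
    truths = link_parameters(shares, cfg, rng)
    if preset == "exp2":
        stimuli = _exp2_stimuli(cfg)
    else:
        stimuli = _exp1_stimuli(cfg)
    truths = generate_true_thresholds(truths, cfg, rng, stimuli)
    records = simulate_trials(truths, cfg, rng)
    fmri_runs: list[tuple[str, BlockTimecourse]] = []
    if preset in ("exp4", "null"):
        truths, fmri_runs = simulate_fmri(truths, cfg, rng)
    return StudyBundle(cfg, parcels, truths, records, fmri_runs)
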