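"""Block-wise ROI response extraction with motion and performance QC.

Stimulus blocks are windows of 12 samples spanning -4 s to +18 s around
onset (at TR = 2 s), converted to percent signal change against the mean of
the three pre-onset samples; the response magnitude is the mean over the
8-12 s samples.  Blocks overlapping framewise displacement above 0.9 mm
(from 8 TRs before onset through 2 TRs after block end, inclusive) are
excluded, and runs lose all blocks when more than half of either
condition's blocks are excluded or the fixation-task hit rate is below 60%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FD_LIMIT_MM",
    "HIT_RATE_LIMIT",
    "BlockTimecourse",
    "BlockWindow",
    "extract_block",
    "psc_transform",
    "response_magnitude",
    "block_motion_qc",
    "run_qc",
    "process_run",
    "subject_response_table",
]

FD_LIMIT_MM = 0.9
HIT_RATE_LIMIT = 0.60
#: TRs of the extraction window before onset and total length (TR = 2 s).
WINDOW_PRE_TR = 2
WINDOW_LEN_TR = 12
#: Baseline: the three samples before stimulus onset.
BASELINE_TR = 3
#: Response readout: samples at 8, 10, 12 s, i.e. window indices 6..8.
RESPONSE_SLICE = slice(6, 9)
#: Motion-QC window margins (TRs) around [onset, block end].
MOTION_PRE_TR = 8
MOTION_POST_TR = 2


@dataclass(frozen=True)
class BlockTimecourse:
    """One run's ROI timecourse plus design and QC covariates."""

    samples: np.ndarray  # ROI signal per TR
    onsets: tuple[int, ...]  # block onset indices (TR units)
    conditions: tuple[str, ...]  # per-block condition label
    fd_mm: np.ndarray  # framewise displacement per TR
    hit_rate: float
    tr_s: float = 2.0
    block_len_tr: int = 5  # stimulus block duration in TRs

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "fd_mm", np.asarray(self.fd_mm, dtype=float))
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if np.any(self.fd_mm < 0):
            raise ValueError("framewise displacement must be nonnegative")
        if not 0 <= self.hit_rate <= 1:
            raise ValueError("hit_rate must lie in [0, 1]")
        if len(self.onsets) != len(self.conditions):
            raise ValueError("onsets and conditions must align")


@dataclass(frozen=True)
class BlockWindow:
    """Extracted 12-sample window, or a skip status when out of range."""

    samples: np.ndarray | None
    status: str  # "ok" | "out_of_range"


def _window_trs(tc: BlockTimecourse) -> tuple[int, int]:
    """Pre-onset and total window length in TRs for this TR (nearest sample)."""
    pre = int(round(WINDOW_PRE_TR * 2.0 / tc.tr_s))
    length = int(round(WINDOW_LEN_TR * 2.0 / tc.tr_s))
    return pre, length


def extract_block(tc: BlockTimecourse, onset: int) -> BlockWindow:
    """Samples at -4, -2, ..., 18 s around onset (12 values at TR = 2 s)."""
    pre, length = _window_trs(tc)
    start = onset - pre
    stop = start + length
    if start < 0 or stop > tc.samples.size:
        return BlockWindow(None, "out_of_range")
    return BlockWindow(tc.samples[start:stop].copy(), "ok")


def psc_transform(block: np.ndarray) -> np.ndarray:
    """Percent signal change against the mean of the 3 pre-onset samples."""
    block = np.asarray(block, dtype=float)
    baseline = block[:BASELINE_TR].mean()
    if baseline <= 0:
        raise ValueError("nonpositive pre-onset baseline")
    return (block - baseline) / baseline * 100.0


def response_magnitude(psc_block: np.ndarray) -> float:
    """Mean percent signal change over the 8-12 s samples (inclusive)."""
    psc_block = np.asarray(psc_block, dtype=float)
    return float(psc_block[RESPONSE_SLICE].mean())


def block_motion_qc(
    tc: BlockTimecourse, onset: int, anchor: str = "end"
) -> bool:
    """True (keep) unless any FD > 0.9 mm in the motion window.

    The window runs from ``onset - 8`` TRs through ``block end + 2`` TRs,
    both inclusive; ``anchor='onset'`` instead ends the window 2 TRs after
    onset.
    """
    if anchor not in ("end", "onset"):
        raise ValueError("anchor must be 'end' or 'onset'")
    end = onset + (tc.block_len_tr - 1 if anchor == "end" else 0)
    lo = max(onset - MOTION_PRE_TR, 0)
    hi = min(end + MOTION_POST_TR, tc.fd_mm.size - 1)
    return not bool(np.any(tc.fd_mm[lo : hi + 1] > FD_LIMIT_MM))


def run_qc(
    block_keep: Sequence[bool], conditions: Sequence[str], hit_rate: float
) -> bool:
    """True (keep run) unless hit rate < 0.6 or more than half of either
    condition's blocks were excluded (exactly half keeps the run)."""
    if hit_rate < HIT_RATE_LIMIT:
        return False
    keep = np.asarray(block_keep, dtype=bool)
    conds = np.asarray(conditions)
    for cond in dict.fromkeys(conditions):
        mask = conds == cond
        n_excluded = int((~keep[mask]).sum())
        if n_excluded * 2 > int(mask.sum()):
            return False
    return True


def process_run(tc: BlockTimecourse) -> pd.DataFrame:
    """Per-block extraction, PSC, response magnitude, and QC for one run.

    Returns a frame with columns block, condition, response, status where
    status is "ok", "motion", "out_of_range", or "run_excluded".
    """
    rows = []
    keep_flags = []
    for onset, cond in zip(tc.onsets, tc.conditions):
        window = extract_block(tc, onset)
        if window.status != "ok":
            rows.append((onset, cond, np.nan, "out_of_range"))
            keep_flags.append(False)
            continue
        if not block_motion_qc(tc, onset):
            rows.append((onset, cond, np.nan, "motion"))
            keep_flags.append(False)
            continue
        resp = response_magnitude(psc_transform(window.samples))
        rows.append((onset, cond, resp, "ok"))
        keep_flags.append(True)
    frame = pd.DataFrame(rows, columns=["onset", "condition", "response", "status"])
    if not run_qc(keep_flags, tc.conditions, tc.hit_rate):
        frame.loc[frame["status"] == "ok", "status"] = "run_excluded"
        frame.loc[:, "response"] = np.nan
    return frame


def subject_response_table(
    runs: Sequence[tuple[str, BlockTimecourse]]
) -> pd.DataFrame:
    """Mean kept-block response per subject and condition.

    ``runs`` holds (subject_id, timecourse) pairs; output columns are
    subject_id, condition, mean_response_pct, n_blocks_kept.
    """
    frames = []
    for subject_id, tc in runs:
        frame = process_run(tc)
        frame.insert(0, "subject_id", subject_id)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["subject_id", "condition", "mean_response_pct", "n_blocks_kept"]
        )
    blocks = pd.concat(frames, ignore_index=True)
    kept = blocks[blocks["status"] == "ok"]
    grouped = (
        kept.groupby(["subject_id", "condition"])["response"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_response_pct", "size": "n_blocks_kept"})
    )
    return grouped
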