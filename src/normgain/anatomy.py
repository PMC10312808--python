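"""Cortical surface-area tables, normalization, region sums, and screening.

A :class:`ParcelTable` is a subject x (hemisphere, parcel) matrix of surface
areas, either raw mm^2 or normalized to percent of the per-hemisphere total
(each subject's parcels within a hemisphere then sum to 100).  Screening
correlates per-parcel normalized surface area against a behavioral variable
and selects parcels passing a sign filter at an uncorrected alpha.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HEMIS",
    "ParcelTable",
    "RegionDef",
    "PARIETAL_REGION",
    "FRONTAL_REGION",
    "ScreenResult",
    "read_parcel_table",
    "normalize_sa",
    "region_sum",
    "group_split",
    "pearson_r",
    "parcel_screen",
    "gap_average",
    "GAP_SMALL",
    "GAP_LARGE",
]

HEMIS = ("LH", "RH")

#: Gap sizes (deg) averaged as "small" and "large" in the integration task.
GAP_SMALL = (0.5, 1.0)
GAP_LARGE = (1.5, 2.5, 4.5)


@dataclass(frozen=True)
class RegionDef:
    """A named set of (hemisphere, parcel) members."""

    name: str
    members: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("region must have at least one member parcel")
        object.__setattr__(self, "members", frozenset(self.members))

    @classmethod
    def of(cls, name: str, hemi: str, parcels: Iterable[str]) -> "RegionDef":
        return cls(name, frozenset((hemi, p) for p in parcels))


#: Right-parietal and left-frontal regions identified by the screening step.
PARIETAL_REGION = RegionDef.of("parietal", "RH", ["7AL", "VIP", "LIPd", "IP1", "IP2"])
FRONTAL_REGION = RegionDef.of("frontal", "LH", ["11l"])


@dataclass
class ParcelTable:
    """Subject x (hemi, parcel) surface areas.

    ``data`` is a wide DataFrame indexed by subject_id with a 2-level
    (hemi, parcel) column MultiIndex.  ``kind`` is "raw" (mm^2) or
    "normalized" (percent of hemisphere total).
    """

    data: pd.DataFrame
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "normalized"):
            raise ValueError("kind must be 'raw' or 'normalized'")
        if self.data.columns.nlevels != 2:
            raise ValueError("columns must be a (hemi, parcel) MultiIndex")
        vals = self.data.to_numpy(dtype=float)
        if self.kind == "raw" and np.any(vals <= 0):
            raise ValueError("raw surface areas must be positive")
        if self.kind == "normalized":
            for hemi in self.hemis:
                sums = self.data[hemi].sum(axis=1)
                if not np.allclose(sums, 100.0, atol=1e-6):
                    raise ValueError(
                        f"normalized {hemi} sums deviate from 100 by more than 1e-6"
                    )

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def hemis(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @classmethod
    def from_long(cls, frame: pd.DataFrame, kind: str = "raw") -> "ParcelTable":
        """Build from a tidy frame: subject_id, hemi, parcel, surfarea_mm2."""
        required = {"subject_id", "hemi", "parcel"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        value_col = "surfarea_mm2" if "surfarea_mm2" in frame.columns else "value"
        if value_col not in frame.columns:
            raise ValueError("missing surface-area value column (surfarea_mm2)")
        dupes = frame.duplicated(subset=["subject_id", "hemi", "parcel"])
        if dupes.any():
            bad = frame.loc[dupes, ["subject_id", "hemi", "parcel"]].iloc[0]
            raise ValueError(
                f"duplicate parcel row: subject {bad.subject_id!r}, "
                f"{bad.hemi} {bad.parcel!r}"
            )
        wide = frame.pivot(
            index="subject_id", columns=["hemi", "parcel"], values=value_col
        )
        wide.index = wide.index.astype(str)
        return cls(wide, kind)

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack(["hemi", "parcel"], future_stack=True).rename(
            "surfarea_mm2"
        )
        long.index.names = ["subject_id", "hemi", "parcel"]
        return long.reset_index()

    def to_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


_FS_HEMI_TOKENS = {"lh": "LH", "rh": "RH"}


def _hemi_from_filename(path: Path) -> str:
    tokens = re.split(r"[._-]", path.name.lower())
    hits = {_FS_HEMI_TOKENS[t] for t in tokens if t in _FS_HEMI_TOKENS}
    if len(hits) != 1:
        raise ValueError(
            f"cannot infer hemisphere from filename {path.name!r}: expected "
            "exactly one 'lh'/'rh' token"
        )
    return hits.pop()


def _read_freesurfer_stats(path: Path) -> pd.DataFrame:
    """Parse a ``mris_anatomical_stats``-style whitespace table.

    Column names are taken from the ``# ColHeaders`` comment when present;
    the table must contain a structure-name column and a ``SurfArea``
    column.  Subject is inferred from the leading filename token and
    hemisphere from an ``lh``/``rh`` filename token.
    """
    header = None
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.lower().startswith("colheaders"):
                header = stripped.split()[1:]
            continue
        if line.strip():
            rows.append(line.split())
    if not rows:
        raise ValueError(f"no data rows in {path}")
    if header is None:
        raise ValueError(f"missing '# ColHeaders' line in {path}")
    frame = pd.DataFrame(rows, columns=header)
    if "SurfArea" not in frame.columns:
        raise ValueError(f"missing SurfArea column in {path}")
    name_col = "StructName" if "StructName" in frame.columns else header[0]
    hemi = _hemi_from_filename(path)
    subject = re.split(r"[._]", path.name)[0]
    return pd.DataFrame(
        {
            "subject_id": subject,
            "hemi": hemi,
            "parcel": frame[name_col].astype(str),
            "surfarea_mm2": frame["SurfArea"].astype(float),
        }
    )


def read_parcel_table(
    paths: str | Path | Sequence[str | Path], dialect: str = "tsv"
) -> ParcelTable:
    """Read surface areas from tidy TSV or FreeSurfer stats files.

    ``dialect='tsv'`` expects a single file with columns subject_id, hemi,
    parcel, surfarea_mm2.  ``dialect='freesurfer_stats'`` accepts one or
    more per-subject-per-hemisphere stats files; subject and hemisphere are
    inferred from each filename.
    """
    if dialect == "tsv":
        if isinstance(paths, (list, tuple)):
            if len(paths) != 1:
                raise ValueError("tsv dialect takes a single file")
            paths = paths[0]
        frame = pd.read_csv(paths, sep="\t", dtype={"subject_id": str})
        return ParcelTable.from_long(frame)
    if dialect == "freesurfer_stats":
        if isinstance(paths, (str, Path)):
            paths = [paths]
        frames = [_read_freesurfer_stats(Path(p)) for p in paths]
        combined = pd.concat(frames, ignore_index=True)
        return ParcelTable.from_long(combined)
    raise ValueError(f"unknown dialect {dialect!r}")


def normalize_sa(table: ParcelTable) -> ParcelTable:
    """Express each parcel as percent of its subject-hemisphere total."""
    if table.kind != "raw":
        raise ValueError("normalize_sa expects a raw table")
    out = table.data.copy().astype(float)
    for hemi in table.hemis:
        totals = out[hemi].sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise ValueError(f"zero {hemi} hemisphere total for subject {bad!r}")
        out[hemi] = out[hemi].div(totals, axis=0) * 100.0
    return ParcelTable(out, kind="normalized")


def region_sum(table: ParcelTable, region: RegionDef) -> pd.Series:
    """Per-subject sum of surface area over the region's member parcels."""
    cols = list(table.data.columns)
    missing = [m for m in sorted(region.members) if m not in cols]
    if missing:
        raise ValueError(f"region {region.name!r} members missing from table: {missing}")
    members = sorted(region.members)
    return table.data[members].sum(axis=1).rename(region.name)


def group_split(values: pd.Series, fraction: float = 1 / 3) -> pd.Series:
    """Rank-based small/large/middle labels.

    With fraction 1/3, the bottom and top n//3 subjects are labeled
    ``small``/``large`` and the rest ``middle``; with 1/2, n//2 each side.
    Ties are broken by stable subject-id order.
    """
    if len(values) < 4:
        raise ValueError("group split needs at least 4 subjects")
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    order = values.reset_index(drop=True)
    idx = sorted(range(len(values)), key=lambda i: (order.iloc[i], str(values.index[i])))
    k = int(len(values) * fraction + 1e-9)
    labels = pd.Series("middle", index=values.index, name="group")
    labels.iloc[[idx[i] for i in range(k)]] = "small"
    labels.iloc[[idx[-(i + 1)] for i in range(k)]] = "large"
    return labels


def pearson_r(x, y) -> tuple[float, float, int]:
    """Pairwise-complete product-moment correlation with two-sided p (df=n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairwise-complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


@dataclass(frozen=True)
class ScreenResult:
    """Per-parcel correlation statistics and the selected subset."""

    stats: pd.DataFrame  # hemi, parcel, r, p, n, selected
    alpha: float
    sign: str

    @property
    def selected(self) -> list[tuple[str, str]]:
        sel = self.stats[self.stats["selected"]]
        return list(zip(sel["hemi"], sel["parcel"]))


def parcel_screen(
    table: ParcelTable,
    behavior: pd.Series,
    alpha: float = 0.01,
    sign: str = "negative",
    one_sided: bool = False,
) -> ScreenResult:
    """Correlate each parcel's surface area with behavior and select.

    p-values are two-sided by default with a separate sign filter; with
    ``one_sided=True`` the p-value is halved when the correlation has the
    requested sign.  Subjects missing behavior are dropped pairwise.
    """
    if sign not in ("negative", "positive", "any"):
        raise ValueError("sign must be 'negative', 'positive', or 'any'")
    common = [s for s in table.subjects if s in behavior.index]
    if len(common) < 10:
        raise ValueError(
            "need at least 10 subjects shared between table and behavior"
        )
    extra = sorted(set(behavior.index) - set(table.subjects))
    if extra:
        raise ValueError(f"behavior contains unknown subjects: {extra[:5]}")
    beh = behavior.loc[common].to_numpy(dtype=float)
    X = table.data.loc[common].to_numpy(dtype=float)
    if np.all(np.isfinite(X)) and np.all(np.isfinite(beh)):
        # vectorized fast path (matches pearson_r; see tests)
        n = len(common)
        xc = X - X.mean(axis=0)
        yc = beh - beh.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        if np.any(denom == 0):
            raise ValueError("zero variance: correlation undefined")
        rs = xc.T @ yc / denom
        rs = np.clip(rs, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            ts = rs * np.sqrt((n - 2) / np.maximum(1 - rs**2, 1e-300))
        ps = 2 * stats.t.sf(np.abs(ts), n - 2)
        stats_iter = [
            (r, p, n) for r, p in zip(rs.tolist(), ps.tolist())
        ]
    else:
        stats_iter = [
            pearson_r(X[:, j], beh) for j in range(X.shape[1])
        ]
    rows = []
    for (hemi, parcel), (r, p, n) in zip(table.data.columns, stats_iter):
        if one_sided:
            right_sign = (r < 0) if sign == "negative" else (r > 0)
            p = p / 2 if (sign == "any" or right_sign) else 1 - p / 2
        ok_sign = {"negative": r < 0, "positive": r > 0, "any": True}[sign]
        rows.append((hemi, parcel, r, p, n, bool(ok_sign and p < alpha)))
    frame = pd.DataFrame(rows, columns=["hemi", "parcel", "r", "p", "n", "selected"])
    return ScreenResult(frame, alpha, sign)


def gap_average(thresholds: Mapping[float, float]) -> tuple[float, float]:
    """Mean threshold over the two smallest and the three largest gap sizes."""
    needed = GAP_SMALL + GAP_LARGE
    missing = [g for g in needed if g not in thresholds]
    if missing:
        raise ValueError(f"missing gap condition(s): {missing}")
    small = float(np.mean([thresholds[g] for g in GAP_SMALL]))
    large = float(np.mean([thresholds[g] for g in GAP_LARGE]))
    return small, large
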