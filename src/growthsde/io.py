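"""Cohort table ingestion, validation, writing and summary reporting.

The on-disk cohort format is a long-format CSV with one row per visit and
mandatory header ``child_id,site,age_months,zwfl`` (UTF-8, comma separator,
'.' decimal).  Lines starting with '#' are provenance comments and are
ignored on read.
"""

from __future__ import annotations

import hashlib
import json
from typing import Sequence

import numpy as np
import pandas as pd

from .models import AgePoint
from .simulate import Trajectory, cohort_to_frame

__all__ = [
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "frame_to_trajectories",
    "cohort_summary",
    "config_hash",
]

REQUIRED_COLUMNS = ["child_id", "site", "age_months", "zwfl"]


class CohortValidationError(ValueError):
    """A cohort table violates the format contract."""


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {missing}")
    df = df[REQUIRED_COLUMNS].copy()
    for col in ("age_months", "zwfl"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise CohortValidationError(
                f"non-numeric {col} at row(s) {bad[:10]}"
            )
        df[col] = vals.astype(float)
    if (df["age_months"] < 0).any():
        bad = df.index[df["age_months"] < 0].tolist()
        raise CohortValidationError(f"negative age_months at row(s) {bad[:10]}")
    if not np.isfinite(df["zwfl"]).all():
        bad = df.index[~np.isfinite(df["zwfl"])].tolist()
        raise CohortValidationError(f"non-finite zwfl at row(s) {bad[:10]}")
    dup = df.duplicated(subset=["child_id", "age_months"], keep=False)
    if dup.any():
        bad = df.index[dup].tolist()
        raise CohortValidationError(
            f"duplicate (child_id, age_months) at row(s) {bad[:10]}"
        )
    multi = df.groupby("child_id")["site"].nunique()
    bad_children = multi[multi > 1].index.tolist()
    if bad_children:
        raise CohortValidationError(
            f"child(ren) appearing at multiple sites: {bad_children[:10]}"
        )
    return df.sort_values(["child_id", "age_months"], kind="mergesort").reset_index(
        drop=True
    )


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    Returns the validated table sorted by child then age.  Violations
    (missing columns, non-numeric ages, duplicate visits, children at two
    sites) raise :class:`CohortValidationError` naming the offending rows.
    """
    df = pd.read_csv(
        path,
        comment="#",
        dtype={"child_id": str, "site": str},
        float_precision="round_trip",
    )
    return _validate_frame(df)


def frame_to_trajectories(df: pd.DataFrame) -> list:
    """Validated cohort table -> list of Trajectory objects."""
    df = _validate_frame(df)
    out = []
    for (cid, site), grp in df.groupby(["child_id", "site"], sort=True):
        pts = tuple(
            AgePoint(a, v) for a, v in zip(grp["age_months"], grp["zwfl"])
        )
        out.append(Trajectory(child_id=str(cid), site=site, points=pts))
    return out


def write_cohort(cohort, path, provenance: dict | None = None) -> None:
    """Write trajectories (or a cohort frame) as long-format CSV with an
    optional provenance comment header."""
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    with open(path, "w") as fh:
        if provenance:
            items = " ".join(f"{k}={v}" for k, v in sorted(provenance.items()))
            fh.write(f"# growthsde cohort {items}\n")
        # shortest round-trip repr, so write -> read is lossless
        df.to_csv(
            fh, index=False, lineterminator="\n",
            float_format=lambda v: repr(float(v)),
        )


def cohort_summary(table) -> dict:
    """Per-site summary of a cohort table.

    For each site: number of children, the visit-count distribution, the
    share of children with >= 24 visits, and monthly cross-sectional
    mean/sd of the z-score with ages binned to the nearest integer month
    (ties to even), bins 0-24.
    """
    if isinstance(table, list):
        table = cohort_to_frame(table)
    df = _validate_frame(table)
    if df.empty:
        raise ValueError("cohort table is empty")
    out = {}
    for site, grp in df.groupby("site", sort=True):
        counts = grp.groupby("child_id").size()
        month = np.round(grp["age_months"]).astype(int)
        in_range = (month >= 0) & (month <= 24)
        monthly = (
            grp.loc[in_range, "zwfl"]
            .groupby(month[in_range])
            .agg(["mean", "std", "count"])
        )
        out[site] = {
            "n_children": int(counts.size),
            "n_visits_total": int(len(grp)),
            "visit_counts": {
                "min": int(counts.min()),
                "median": float(counts.median()),
                "max": int(counts.max()),
            },
            "share_ge_24_visits": float((counts >= 24).mean()),
            "monthly_mean": {int(m): float(v) for m, v in monthly["mean"].items()},
            "monthly_sd": {
                int(m): (float(v) if np.isfinite(v) else 0.0)
                for m, v in monthly["std"].fillna(0.0).items()
            },
            "monthly_n": {int(m): int(v) for m, v in monthly["count"].items()},
        }
    return out
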