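"""Cohort summary statistics for mould-biopsy study tables.

Operates on a per-patient table (PSA, PSA density, prostate size, PI-RADS,
lesion volumes, and the Gleason Grade Group from the original diagnostic
biopsy vs. from the mould-guided ex vivo biopsy).  A transcription of the
12-patient feasibility cohort ships with the package as ``data/table1.csv``.

Reported medians follow the convention of clinical tables: the midpoint of
the two central order statistics for even n, rounded half-away-from-zero to
the printed precision (2 dp for PSA and PSA density, 1 dp for prostate
size) — banker's rounding would mis-report midpoints like 0.175.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "patient", "psa_ng_ml", "psa_density", "prostate_size_cc", "pirads",
    "lesion_volumes_cc", "lesion_location", "clinical_gg", "mould_gg",
)


@dataclasses.dataclass
class CohortSummary:
    n: int
    median_psa: float
    psa_range: tuple[float, float]
    median_psa_density: float
    psa_density_range: tuple[float, float]
    median_size_cc: float
    size_range_cc: tuple[float, float]
    positivity_fraction: float
    concordance_fraction: float


def load_cohort(path: str | Path | None = None) -> pd.DataFrame:
    """Load a cohort table (the packaged fixture when ``path`` is None).

    ``lesion_volumes_cc`` may hold several semicolon-separated volumes for
    multifocal cases; it is parsed into a list of floats.  ``mould_gg`` is
    nullable: a missing value means the mould biopsy found no cancer.
    """
    if path is None:
        with resources.as_file(
                resources.files("prostmould.data") / "table1.csv") as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df["lesion_volumes_cc"] = df["lesion_volumes_cc"].astype(str).apply(
        lambda s: [float(v) for v in s.split(";") if v.strip()])
    df["mould_gg"] = pd.to_numeric(df["mould_gg"], errors="coerce")
    for col, lo, hi in (("pirads", 3, 5), ("clinical_gg", 1, 5)):
        bad = ~df[col].between(lo, hi)
        if bad.any():
            raise ValueError(f"{col} outside {lo}..{hi} in rows "
                             f"{df.index[bad].tolist()}")
    present = df["mould_gg"].dropna()
    if ((present < 1) | (present > 5)).any():
        raise ValueError("mould_gg outside 1..5")
    if (df["psa_density"] <= 0).any():
        raise ValueError("psa_density must be positive")
    return df


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _median(values: np.ndarray) -> float:
    """Midpoint of the two central order statistics for even n."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("median of an empty column")
    mid = n // 2
    return float(v[mid]) if n % 2 else float((v[mid - 1] + v[mid]) / 2.0)


def positivity(table: pd.DataFrame) -> float:
    """Fraction of patients whose mould biopsy found cancer (any grade
    recorded)."""
    return float(table["mould_gg"].notna().mean())


def concordance(table: pd.DataFrame) -> float:
    """Fraction of patients whose mould-biopsy grade group equals the
    original diagnostic biopsy grade group.  Requires both grades."""
    if table["mould_gg"].isna().any():
        rows = table.index[table["mould_gg"].isna()].tolist()
        raise ValueError(f"mould_gg missing in rows {rows}; concordance "
                         f"needs both grades")
    return float((table["clinical_gg"] == table["mould_gg"]).mean())


def summarize(table: pd.DataFrame) -> CohortSummary:
    """Medians, ranges, positivity and grade concordance for a cohort."""
    if len(table) == 0:
        raise ValueError("empty cohort table")
    psa = table["psa_ng_ml"].to_numpy(float)
    dens = table["psa_density"].to_numpy(float)
    size = table["prostate_size_cc"].to_numpy(float)
    return CohortSummary(
        n=len(table),
        median_psa=_round_half_up(_median(psa), 2),
        psa_range=(float(psa.min()), float(psa.max())),
        median_psa_density=_round_half_up(_median(dens), 2),
        psa_density_range=(float(dens.min()), float(dens.max())),
        median_size_cc=_round_half_up(_median(size), 1),
        size_range_cc=(float(size.min()), float(size.max())),
        positivity_fraction=positivity(table),
        concordance_fraction=float(
            (table["clinical_gg"] == table["mould_gg"]).mean()),
    )
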