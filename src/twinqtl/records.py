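"""Validation, filtering and model-frame encoding of birth records.

The response is the 1/2 coding of the multiple-birth outcome (1 = single
birth, 2 = twin or triplet).  Filtering reproduces the national-evaluation
data preparation: embryo-transfer records dropped first, then herds with
fewer than 260 records, then (optionally) herd-year classes with fewer
than five records; each count is evaluated on the set surviving the
previous rule, making the herd-year rule a refinement of the herd rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .pedigree import Pedigree

PARITY_LEVELS = ["1", "2", "3", "4", "5+"]
SEASON_LEVELS = ["spring", "summer", "fall", "winter"]
SEXED_LEVELS = ["no", "yes"]


class RecordError(ValueError):
    pass


@dataclass
class FilterReport:
    n_input: int
    removed_embryo_transfer: int = 0
    removed_small_herd: int = 0
    removed_small_herd_year: int = 0
    n_retained: int = 0

    @property
    def conserved(self) -> bool:
        removed = (
            self.removed_embryo_transfer
            + self.removed_small_herd
            + self.removed_small_herd_year
        )
        return removed + self.n_retained == self.n_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["embryo_transfer", "small_herd", "small_herd_year",
                         "retained"],
                "count": [
                    self.removed_embryo_transfer,
                    self.removed_small_herd,
                    self.removed_small_herd_year,
                    self.n_retained,
                ],
            }
        )


def _require_columns(records: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise RecordError(f"records lack required columns {missing}")


def filter_records(
    records: pd.DataFrame,
    min_herd_records: int = 260,
    min_herd_year_records: Optional[int] = None,
    drop_embryo_transfer: bool = True,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Apply the evaluation filters in order ET -> herd -> herd-year.

    ``min_herd_year_records=None`` reproduces the breeding-value dataset
    (herd filter only); ``min_herd_year_records=5`` reproduces the
    variance-component dataset.
    """
    _require_columns(records, ["herd", "year"])
    if records[["herd", "year"]].isna().any().any():
        bad = records.index[records[["herd", "year"]].isna().any(axis=1)][:5]
        raise RecordError(f"records with missing herd/year fields: {list(bad)}")
    report = FilterReport(n_input=len(records))
    kept = records
    if drop_embryo_transfer and "embryo_transfer" in records.columns:
        et = kept["embryo_transfer"].fillna(False).astype(bool)
        report.removed_embryo_transfer = int(et.sum())
        kept = kept[~et]
    herd_n = kept.groupby("herd")["herd"].transform("size")
    small = herd_n < min_herd_records
    report.removed_small_herd = int(small.sum())
    kept = kept[~small]
    if min_herd_year_records is not None:
        hy_n = kept.groupby(["herd", "year"])["herd"].transform("size")
        small = hy_n < min_herd_year_records
        report.removed_small_herd_year = int(small.sum())
        kept = kept[~small]
    report.n_retained = len(kept)
    return kept.copy(), report


def multiple_birth_rate(records: pd.DataFrame) -> float:
    """Proportion of records with multiple-birth code 2."""
    if len(records) == 0:
        raise RecordError("cannot compute a rate on an empty record set")
    _require_columns(records, ["code"])
    return float((records["code"].to_numpy() == 2).mean())


@dataclass
class ModelFrame:
    """Encoded design information for the animal model.

    ``data`` holds the response and factor codes; level orderings are fixed
    (parity 1..5+, season spring/summer/fall/winter, sexed no/yes) so that
    downstream design matrices and reported solutions are reproducible.
    """

    data: pd.DataFrame
    parity_levels: list = field(default_factory=lambda: list(PARITY_LEVELS))
    season_levels: list = field(default_factory=lambda: list(SEASON_LEVELS))
    sexed_levels: list = field(default_factory=lambda: list(SEXED_LEVELS))

    def level_counts(self) -> pd.DataFrame:
        """Observation counts per fixed-effect level."""
        rows = []
        for factor, levels in (
            ("parity", self.parity_levels),
            ("sexed_semen", self.sexed_levels),
            ("season", self.season_levels),
        ):
            counts = self.data[factor].value_counts()
            for lev in levels:
                rows.append((factor, lev, int(counts.get(lev, 0))))
        return pd.DataFrame(rows, columns=["factor", "level", "n"])


def encode_model_frame(records: pd.DataFrame, pedigree: Pedigree) -> ModelFrame:
    """Build the model frame: 1/2 response, fixed factors, ids.

    Parities above 5 are capped into the "5+" level; a missing sexed-semen
    flag defaults to "no" (the dominant level).  Every dam must be present
    in the pedigree.
    """
    _require_columns(records, ["calf", "dam", "herd", "year", "season",
                               "parity", "age_of_dam", "code"])
    ped_ids = set(int(i) for i in pedigree.ids)
    dams = records["dam"].to_numpy()
    missing = sorted({int(d) for d in dams if int(d) not in ped_ids})
    if missing:
        raise RecordError(f"dams absent from pedigree: {missing[:10]}")
    calves = records["calf"].to_numpy()
    missing = sorted({int(c) for c in calves if int(c) not in ped_ids})
    if missing:
        raise RecordError(f"calves absent from pedigree: {missing[:10]}")

    parity = np.minimum(records["parity"].to_numpy(dtype=int), 5)
    parity_lab = np.where(parity >= 5, "5+", parity.astype(str))
    if "sexed_semen" in records.columns:
        sexed = records["sexed_semen"].fillna(False).astype(bool).to_numpy()
    else:
        sexed = np.zeros(len(records), dtype=bool)
    season = records["season"].astype(str).str.lower()
    bad = ~season.isin(SEASON_LEVELS)
    if bad.any():
        raise RecordError(f"unknown season labels: {sorted(season[bad].unique())}")

    data = pd.DataFrame(
        {
            "y": records["code"].to_numpy(dtype=float),
            "parity": pd.Categorical(parity_lab, categories=PARITY_LEVELS),
            "season": pd.Categorical(season, categories=SEASON_LEVELS),
            "sexed_semen": pd.Categorical(
                np.where(sexed, "yes", "no"), categories=SEXED_LEVELS
            ),
            "herd_year": pd.Categorical(
                records["herd"].astype(str) + ":" + records["year"].astype(str)
            ),
            "age_of_dam": records["age_of_dam"].to_numpy(dtype=float),
            "calf": records["calf"].to_numpy(),
            "dam": records["dam"].to_numpy(),
        }
    )
    return ModelFrame(data=data)
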