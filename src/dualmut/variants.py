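"""Typed variant collections.

A :class:`VariantSet` is a thin frame of point positions of three kinds:
germline SNPs (carry an allele frequency; rare means AF < 0.01), somatic
mutations (carry a patient id), and disease variants (bare positions from a
curated catalogue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RARE_AF_THRESHOLD = 0.01

KINDS = ("germline", "somatic", "disease")
COLUMNS = ["chrom", "pos", "kind", "af", "patient_id"]


@dataclass
class VariantSet:
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        bad = set(self.df["kind"].unique()) - set(KINDS)
        if bad:
            raise ValueError(f"unknown variant kind(s): {sorted(bad)}")
        germ = self.df[self.df["kind"] == "germline"]
        if germ["af"].isna().any():
            raise ValueError("germline records must carry an allele frequency")
        som = self.df[self.df["kind"] == "somatic"]
        if som["patient_id"].isna().any():
            raise ValueError("somatic records must carry a patient id")

    @classmethod
    def empty(cls) -> "VariantSet":
        return cls(
            pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "pos": pd.Series(dtype=np.int64),
                    "kind": pd.Series(dtype=str),
                    "af": pd.Series(dtype=float),
                    "patient_id": pd.Series(dtype=object),
                }
            )
        )

    @classmethod
    def from_arrays(cls, chrom, pos, kind, af=None, patient_id=None) -> "VariantSet":
        n = len(pos)
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chrom, dtype=object),
                "pos": np.asarray(pos, dtype=np.int64),
                "kind": kind if not np.isscalar(kind) else np.repeat(kind, n),
                "af": np.full(n, np.nan) if af is None else np.asarray(af, dtype=float),
                "patient_id": np.full(n, None, dtype=object)
                if patient_id is None
                else np.asarray(patient_id, dtype=object),
            }
        )
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def of_kind(self, kind: str) -> "VariantSet":
        return VariantSet(self.df[self.df["kind"] == kind].reset_index(drop=True))

    @property
    def is_rare(self) -> np.ndarray:
        """Rare flag for germline records (AF below the rare threshold)."""
        return (self.df["af"].to_numpy() < RARE_AF_THRESHOLD) & (
            self.df["kind"].to_numpy() == "germline"
        )

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    @property
    def n_patients(self) -> int:
        som = self.df[self.df["kind"] == "somatic"]
        return int(som["patient_id"].nunique())
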