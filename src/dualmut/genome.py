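"""Genome coordinate model: chromosome names/lengths and excluded regions.

Excluded regions play the role of telomere/centromere/stalk/pericentromere
analogues and fully-unassembled sequence: 1 Mb model windows overlapping them
are never used for training or prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import FeatureTrack


@dataclass
class GenomeModel:
    chromosomes: list[tuple[str, int]]
    excluded: FeatureTrack = field(default_factory=lambda: FeatureTrack("excluded"))

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length {length}")
        lengths = self.lengths
        for chrom, s, e in self.excluded.iter_intervals():
            if chrom not in lengths or e > lengths[chrom]:
                raise ValueError(f"excluded region ({chrom}, {s}, {e}) out of bounds")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def analyzed_bp(self) -> int:
        """Genome size minus excluded regions."""
        return self.total_size - self.excluded.total_bp()

    def validate_positions(self, chrom_arr, pos_arr) -> None:
        lengths = self.lengths
        for chrom in np.unique(np.asarray(chrom_arr)):
            if chrom not in lengths:
                raise ValueError(f"unknown chromosome {chrom!r}")
            pos = np.asarray(pos_arr)[np.asarray(chrom_arr) == chrom]
            if len(pos) and (pos.min() < 0 or pos.max() >= lengths[chrom]):
                raise ValueError(f"position out of bounds on {chrom}")
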