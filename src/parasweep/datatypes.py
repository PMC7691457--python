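"""Core in-memory containers shared across the pipeline.

Conventions:

* coordinates are 1-based inclusive internally (VCF convention); every BED
  emitted by the package converts to 0-based half-open;
* haplotype matrices are coded 0 = ancestral, 1 = derived, -1 = missing,
  with exactly two rows per diploid sample (rows ``2i`` and ``2i+1``);
* the site table is a pandas DataFrame, one row per retained site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

MISSING = -1

#: SiteTable columns always present (per-population AFs are ``af_<pop>``).
SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "ancestral_allele",
    "mean_depth",
    "rms_mapping_quality",
    "missing_ratio",
    "functional_class",
    "gene_symbol",
]


@dataclass
class HaplotypeBlock:
    """Phased allele matrix (haplotypes x sites) for one chromosome."""

    chrom: str
    positions: np.ndarray  # int64, 1-based, strictly increasing
    alleles: np.ndarray    # int8 (2*n_samples, n_sites); 0/1/-1
    sample_ids: List[str]

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (2 * len(self.sample_ids), len(self.positions)):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.positions)} sites"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError(f"{self.chrom}: positions not strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def sample_of_haplotype(self, hap_index: int) -> str:
        return self.sample_ids[hap_index // 2]

    def haplotype_rows(self, samples: List[str]) -> np.ndarray:
        """Row indices of the two haplotypes of each listed sample."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in samples:
            i = index[s]
            rows.extend((2 * i, 2 * i + 1))
        return np.asarray(rows, dtype=np.int64)

    def take_sites(self, mask: np.ndarray) -> "HaplotypeBlock":
        return HaplotypeBlock(
            chrom=self.chrom,
            positions=self.positions[mask],
            alleles=self.alleles[:, mask],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class PopulationMap:
    """Sample -> population assignment with a stable population order."""

    assignments: Dict[str, str]
    populations: List[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.populations:
            seen: List[str] = []
            for pop in self.assignments.values():
                if pop not in seen:
                    seen.append(pop)
            self.populations = seen
        if len(self.populations) < 2:
            raise ValueError("population map must define at least 2 populations")

    def samples(self, pop: str) -> List[str]:
        return [s for s, p in self.assignments.items() if p == pop]

    @classmethod
    def read_tsv(cls, path) -> "PopulationMap":
        assignments: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sample, pop = line.split("\t")[:2]
                if sample in assignments:
                    raise ValueError(f"sample {sample!r} assigned twice in {path}")
                assignments[sample] = pop
        return cls(assignments)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self.assignments.items():
                fh.write(f"{sample}\t{pop}\n")


def empty_site_table(populations: List[str]) -> pd.DataFrame:
    cols = SITE_COLUMNS + [f"af_{p}" for p in populations]
    return pd.DataFrame(columns=cols)
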