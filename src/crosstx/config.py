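"""Run configuration shared by every pipeline stage.

All thresholds of the analysis live here so that a run is fully described
by one flat, serialisable mapping: the differential-expression cutoffs
(fold change > 1.5 or < 1/1.5 with p < 0.05), the connectivity-query
signature bounds (10-150 valid up-regulated genes), the reverser score
window ([-100, -80]), the cross-dataset overlap minima for "interested"
drugs, and the permutation-test replicate count.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Tuple

import yaml

VALID_DIALECTS = ("corr_rows", "direct")
VALID_FDR = ("none", "bh")
VALID_DISTANCE_SPACES = ("embedding", "input")


@dataclass
class RunConfig:
    """Resolved configuration for one analysis run.

    Parameters
    ----------
    fc_threshold
        Fold-change cutoff; a gene is "up" when fc > this value and
        "down" when fc < 1/this value (strict inequalities).
    p_threshold
        Rank-sum p-value cutoff (strict), also used for enrichment.
    signature_min, signature_max
        Valid-up-gene bounds for a connectivity query signature.
    score_window
        Closed interval of connectivity scores selecting reversers.
    human_overlap_min, animal_overlap_min
        Minimum number of per-dataset candidate lists a drug must appear
        in to become an "interested" drug, for each dataset group.
    n_permutations
        Replicates for permutation / resampling nulls.
    seed
        Base seed for every stochastic stage.
    distance_dialect
        How correlation becomes distance: Euclidean distance between
        correlation-matrix rows (``corr_rows``) or sqrt(2(1-rho))
        (``direct``).
    fdr
        ``bh`` switches on Benjamini-Hochberg adjustment of DE and
        enrichment p-values; off by default.
    mds_distance_space
        Whether the tissue-distance test measures distances in the 2-D
        MDS embedding or on the input distance matrix.
    """

    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    signature_min: int = 10
    signature_max: int = 150
    score_window: Tuple[float, float] = (-100.0, -80.0)
    human_overlap_min: int = 4
    animal_overlap_min: int = 5
    n_permutations: int = 10000
    seed: int = 0
    distance_dialect: str = "corr_rows"
    fdr: str = "none"
    mds_distance_space: str = "embedding"
    min_datasets: int = 3
    min_overlap: int = 2
    min_common_genes: int = 100

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        if not 0 < self.p_threshold < 1:
            raise ValueError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if not self.signature_min < self.signature_max:
            raise ValueError("signature_min must be < signature_max")
        lo, hi = self.score_window
        if not lo < hi:
            raise ValueError(f"score_window must satisfy lo < hi, got {self.score_window}")
        self.score_window = (float(lo), float(hi))
        if self.distance_dialect not in VALID_DIALECTS:
            raise ValueError(f"distance_dialect must be one of {VALID_DIALECTS}")
        if self.fdr not in VALID_FDR:
            raise ValueError(f"fdr must be one of {VALID_FDR}")
        if self.mds_distance_space not in VALID_DISTANCE_SPACES:
            raise ValueError(f"mds_distance_space must be one of {VALID_DISTANCE_SPACES}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["score_window"] = list(self.score_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "score_window" in d:
            d["score_window"] = tuple(d["score_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
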