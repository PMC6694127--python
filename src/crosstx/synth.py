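"""Synthetic multi-cohort expression data with planted, known structure.

The generator emulates the statistical shape of a multi-cohort
case/control microarray compendium: several small cohorts per tissue,
log2-scale Gaussian intensities around gene baselines shared across
cohorts, per-dataset gene dropout standing in for platform-universe
differences, and planted gene sets whose case effect has a
tissue-dependent sign (e.g. up-regulated in brain cohorts, down in
blood).  Because the baselines are shared, fold-change vectors — not
absolute levels — carry the cross-dataset signal, which is exactly what
the similarity stage measures.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml

from .io import (
    DrugProfileCatalogue,
    DrugSetDB,
    ExpressionDataset,
    GeneSetDB,
    write_drug_catalogue,
    write_drugset_gmt,
    write_expression_dataset,
    write_gmt,
)


@dataclass
class SynthDesign:
    """Blueprint for one synthetic compendium.

    ``tissues`` lists (label, n_datasets, n_case, n_control);
    ``planted_sets`` lists (name, gene indices, {tissue: signed log2
    effect}).  ``dropout_frac`` is the fraction of non-planted genes
    absent from each dataset, emulating platform differences.
    """

    n_genes: int = 1000
    tissues: List[Tuple[str, int, int, int]] = field(
        default_factory=lambda: [("brain", 4, 10, 10), ("blood", 4, 10, 10)]
    )
    planted_sets: List[Tuple[str, List[int], Dict[str, float]]] = field(
        default_factory=lambda: [
            ("immune_response", list(range(0, 60)), {"brain": 2.0, "blood": -2.0}),
            ("oxidative_phosphorylation", list(range(60, 100)), {"brain": -2.0, "blood": -2.0}),
        ]
    )
    baseline_mu_sd: Tuple[float, float] = (8.0, 2.0)
    noise_sd: float = 0.5
    dropout_frac: float = 0.1
    organism: str = "human"
    id_prefix: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("design needs at least one gene")
        if not self.tissues or sum(t[1] for t in self.tissues) == 0:
            raise ValueError("design needs at least one dataset")
        if not 0 <= self.dropout_frac < 1:
            raise ValueError("dropout_frac must be in [0, 1)")
        seen: set = set()
        for name, idx, _ in self.planted_sets:
            s = set(idx)
            if s & seen:
                raise ValueError(f"planted set '{name}' overlaps another planted set")
            if max(s, default=-1) >= self.n_genes:
                raise ValueError(f"planted set '{name}' indexes beyond n_genes")
            seen |= s
        if self.dropout_frac > 0 and (self.n_genes - self._n_droppable()) < 0.5 * self.n_genes:
            raise ValueError("dropout would leave < 50% of genes in a dataset")

    def _n_droppable(self) -> int:
        n_planted = sum(len(idx) for _, idx, _ in self.planted_sets)
        return int(round(self.dropout_frac * (self.n_genes - n_planted)))

    @property
    def planted_indices(self) -> np.ndarray:
        out: List[int] = []
        for _, idx, _ in self.planted_sets:
            out.extend(idx)
        return np.asarray(sorted(out), dtype=int)

    def gene_symbols(self) -> List[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def generate_datasets(design: SynthDesign) -> List[ExpressionDataset]:
    """Simulate every cohort of the design; deterministic given the seed.

    value(g, sample) = baseline_g + case * delta(g, tissue) +
    Normal(0, noise_sd) on log2 scale.  Baselines are drawn once
    globally; each dataset keeps all planted genes but loses a random
    ``dropout_frac`` of the remaining genes.
    """
    rng = np.random.default_rng(design.seed)
    mu, sd = design.baseline_mu_sd
    baseline = rng.normal(mu, sd, design.n_genes)
    symbols = np.asarray(design.gene_symbols())

    delta_by_tissue: Dict[str, np.ndarray] = {}
    for tissue, _, _, _ in design.tissues:
        delta = np.zeros(design.n_genes)
        for _, idx, effects in design.planted_sets:
            delta[np.asarray(idx, dtype=int)] = effects.get(tissue, 0.0)
        delta_by_tissue[tissue] = delta

    planted = set(design.planted_indices.tolist())
    droppable = np.asarray([i for i in range(design.n_genes) if i not in planted])
    n_drop = design._n_droppable()

    datasets: List[ExpressionDataset] = []
    for tissue, n_datasets, n_case, n_control in design.tissues:
        for d in range(1, n_datasets + 1):
            if n_drop > 0:
                drop = rng.choice(droppable, size=n_drop, replace=False)
                keep = np.setdiff1d(np.arange(design.n_genes), drop)
            else:
                keep = np.arange(design.n_genes)
            n_s = n_case + n_control
            case_ind = np.concatenate([np.ones(n_case), np.zeros(n_control)])
            values = (
                baseline[keep, None]
                + delta_by_tissue[tissue][keep, None] * case_ind[None, :]
                + rng.normal(0.0, design.noise_sd, (keep.size, n_s))
            )
            samples = [f"{tissue}{d}_s{i + 1}" for i in range(n_s)]
            group = {
                s: ("case" if i < n_case else "control") for i, s in enumerate(samples)
            }
            datasets.append(
                ExpressionDataset(
                    dataset_id=f"{design.id_prefix}{tissue}_{d}",
                    tissue=tissue,
                    organism=design.organism,
                    platform_id=f"SIMPL_{tissue}_{d}",
                    scale="log2",
                    genes=symbols[keep].tolist(),
                    samples=samples,
                    values=values,
                    group=group,
                )
            )
    return datasets


def generate_genesets(
    design: SynthDesign,
    n_random_terms: int,
    term_size_range: Tuple[int, int] = (20, 50),
    seed: int = 0,
) -> GeneSetDB:
    """One exact-membership term per planted set plus uniform random terms."""
    lo, hi = term_size_range
    if hi > design.n_genes:
        raise ValueError("term sizes must not exceed n_genes")
    rng = np.random.default_rng(seed)
    symbols = design.gene_symbols()
    entries = [
        (name, "planted", frozenset(symbols[i] for i in idx))
        for name, idx, _ in design.planted_sets
    ]
    width = len(str(max(n_random_terms, 1)))
    for t in range(1, n_random_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(design.n_genes, size=size, replace=False)
        entries.append(
            (f"RAND{t:0{width}d}", "random", frozenset(symbols[i] for i in members))
        )
    return GeneSetDB(entries)


def generate_drug_catalogue(
    gene_universe: Sequence[str],
    n_random_drugs: int,
    planted: Sequence[Tuple[str, str, Tuple[Sequence[str], Sequence[str]]]] = (),
    seed: int = 0,
) -> DrugProfileCatalogue:
    """Random ranked drug profiles plus planted reversers/mimickers.

    A reverser for a signature (up, down) places the signature's down
    genes in the top profile ranks and its up genes at the bottom (a
    mimicker does the opposite); all other genes are shuffled between.
    Random drugs are uniform permutations of the universe.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(gene_universe)
    index = {g: i for i, g in enumerate(universe)}
    n = len(universe)
    profiles: Dict[str, np.ndarray] = {}
    width = len(str(max(n_random_drugs, 1)))
    for d in range(1, n_random_drugs + 1):
        profiles[f"drug_{d:0{width}d}"] = rng.permutation(n)
    for name, role, (up, down) in planted:
        if name in profiles:
            raise ValueError(f"planted drug name '{name}' collides with a random drug")
        if role not in ("reverser", "mimicker"):
            raise ValueError(f"unknown planted role '{role}'")
        up_idx = np.asarray([index[g] for g in up], dtype=int)
        down_idx = np.asarray([index[g] for g in down], dtype=int)
        rest = np.setdiff1d(np.arange(n), np.concatenate([up_idx, down_idx]))
        rest = rng.permutation(rest)
        top, bottom = (down_idx, up_idx) if role == "reverser" else (up_idx, down_idx)
        profiles[name] = np.concatenate(
            [rng.permutation(top), rest, rng.permutation(bottom)]
        )
    return DrugProfileCatalogue(gene_universe=universe, profiles=profiles)


def generate_drugsets(
    drug_names: Sequence[str],
    planted_members: Sequence[str],
    n_random_sets: int = 20,
    set_size_range: Tuple[int, int] = (5, 25),
    seed: int = 0,
) -> DrugSetDB:
    """A drug-set database with one planted target set plus random sets."""
    rng = np.random.default_rng(seed)
    drugs = list(drug_names)
    lo, hi = set_size_range
    entries = []
    if planted_members:
        entries.append(("PLANTED_TARGET", "target", frozenset(planted_members)))
    for t in range(1, n_random_sets + 1):
        size = int(rng.integers(lo, min(hi, len(drugs)) + 1))
        members = rng.choice(len(drugs), size=size, replace=False)
        entries.append((f"DSET{t:03d}", "other", frozenset(drugs[i] for i in members)))
    return DrugSetDB(entries)


# ---------------------------------------------------------------------------
# full simulation layout for the pipeline
# ---------------------------------------------------------------------------

def planted_signature(design: SynthDesign) -> Tuple[List[str], List[str]]:
    """The brain-direction signature of the design's planted sets.

    Up genes come from planted sets with a positive "brain" effect, down
    genes from sets with a negative one — the signature a brain cohort's
    DE stage should rediscover.
    """
    symbols = design.gene_symbols()
    up: List[str] = []
    down: List[str] = []
    for _, idx, effects in design.planted_sets:
        delta = effects.get("brain", 0.0)
        if delta > 0:
            up.extend(symbols[i] for i in idx)
        elif delta < 0:
            down.extend(symbols[i] for i in idx)
    return up, down


def write_simulation(
    designs: SynthDesign | Sequence[SynthDesign],
    outdir: str | Path,
    n_random_terms: int = 100,
    n_random_drugs: int = 500,
    n_planted_reversers: int = 5,
    group_names: Sequence[str] = ("human", "animal"),
) -> Path:
    """Emit the directory layout consumed by ``run-all``.

    One design produces a single-group compendium; a sequence of designs
    (sharing ``n_genes``) produces one dataset group per design, which
    switches on the cross-group permutation stage downstream.  Planted
    reversers target the first design's brain-direction signature, so
    brain cohorts should rediscover them in the connectivity stage.
    """
    import pandas as pd

    if isinstance(designs, SynthDesign):
        designs = [designs]
    if len({d.n_genes for d in designs}) != 1:
        raise ValueError("all designs must share n_genes (one gene universe)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for design, group in zip(designs, group_names):
        for ds in generate_datasets(design):
            write_expression_dataset(
                ds,
                outdir / f"{ds.dataset_id}.matrix.tsv",
                outdir / f"{ds.dataset_id}.phenotype.tsv",
            )
            rows.append(
                {
                    "dataset_id": ds.dataset_id,
                    "tissue": ds.tissue,
                    "organism": ds.organism,
                    "platform_id": ds.platform_id,
                    "scale": ds.scale,
                    "matrix": f"{ds.dataset_id}.matrix.tsv",
                    "phenotype": f"{ds.dataset_id}.phenotype.tsv",
                    "group": group,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "datasets.tsv", sep="\t", index=False)

    lead = designs[0]
    db = generate_genesets(lead, n_random_terms=n_random_terms, seed=lead.seed + 1)
    write_gmt(db, outdir / "genesets.gmt")

    sig_up, sig_down = planted_signature(lead)
    planted = [
        (f"planted_reverser_{i}", "reverser", (sig_up, sig_down))
        for i in range(1, n_planted_reversers + 1)
    ]
    cat = generate_drug_catalogue(lead.gene_symbols(), n_random_drugs, planted, seed=lead.seed + 2)
    write_drug_catalogue(cat, outdir / "catalogue.tsv")

    dsdb = generate_drugsets(cat.drugs, [p[0] for p in planted], seed=lead.seed + 3)
    write_drugset_gmt(dsdb, outdir / "drugsets.gmt")

    with open(outdir / "design.yaml", "w") as fh:
        yaml.safe_dump(
            [
                {
                    "n_genes": d.n_genes,
                    "tissues": [list(t) for t in d.tissues],
                    "noise_sd": d.noise_sd,
                    "dropout_frac": d.dropout_frac,
                    "organism": d.organism,
                    "id_prefix": d.id_prefix,
                    "seed": d.seed,
                }
                for d in designs
            ],
            fh,
        )
    return outdir
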