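"""Readers, writers and validated in-memory containers for all on-disk formats.

Formats handled here:

* expression matrix — TSV, genes x samples, header row of sample ids,
  first column ``gene``;
* phenotype table — TSV with columns ``sample_id``, ``group`` where group
  is ``case`` or ``control``;
* gene sets / drug sets — GMT (term, description, members...);
* drug catalogue — TSV, one row per drug: drug name followed by the full
  ordered gene list (rank 1 = most up-regulated by the drug).

Parsing is locale-independent (decimal point only) and tolerates both LF
and CRLF line endings.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HUMAN_ORGANISMS = {"human", "homo sapiens"}

#: minimum samples per group: 2 for human cohorts, 5 (i.e. "greater than
#: four") for animal-model cohorts.
MIN_GROUP_HUMAN = 2
MIN_GROUP_ANIMAL = 5


class ValidationError(ValueError):
    """A dataset or database violates one of its structural invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """One case/control cohort: gene x sample matrix plus metadata.

    ``scale`` records whether ``values`` are linear intensities or
    log2-transformed; fold changes are computed accordingly downstream.
    """

    dataset_id: str
    tissue: str
    organism: str
    platform_id: str
    scale: str  # "linear" | "log2"
    genes: List[str]
    samples: List[str]
    values: np.ndarray  # genes x samples
    group: Dict[str, str]  # sample -> "case" | "control"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"{self.dataset_id}: scale must be 'linear' or 'log2'")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.dataset_id}: non-finite expression values")
        if self.scale == "linear" and np.any(self.values < 0):
            raise ValidationError(f"{self.dataset_id}: negative values on linear scale")
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)[pd.Index(self.genes).duplicated()].unique()
            raise ValidationError(f"{self.dataset_id}: duplicate gene symbols {list(dupes)[:5]}")
        missing = [s for s in self.samples if s not in self.group]
        if missing:
            raise ValidationError(
                f"{self.dataset_id}: sample '{missing[0]}' has no phenotype group"
            )
        bad = {s: g for s, g in self.group.items() if g not in ("case", "control")}
        if bad:
            raise ValidationError(f"{self.dataset_id}: invalid group labels {bad}")
        n_case = sum(1 for s in self.samples if self.group[s] == "case")
        n_control = len(self.samples) - n_case
        min_n = MIN_GROUP_HUMAN if self.is_human else MIN_GROUP_ANIMAL
        if n_case < min_n or n_control < min_n:
            if self.is_human:
                raise ValidationError(
                    f"{self.dataset_id}: each group needs >= {min_n} samples "
                    f"(got {n_case} case / {n_control} control)"
                )
            raise ValidationError(
                f"{self.dataset_id}: group size must exceed 4 for animal datasets "
                f"(got {n_case} case / {n_control} control)"
            )

    # -- convenience --------------------------------------------------------
    @property
    def is_human(self) -> bool:
        return self.organism.strip().lower() in HUMAN_ORGANISMS

    @property
    def case_samples(self) -> List[str]:
        return [s for s in self.samples if self.group[s] == "case"]

    @property
    def control_samples(self) -> List[str]:
        return [s for s in self.samples if self.group[s] == "control"]

    def case_matrix(self) -> np.ndarray:
        idx = [self.samples.index(s) for s in self.case_samples]
        return self.values[:, idx]

    def control_matrix(self) -> np.ndarray:
        idx = [self.samples.index(s) for s in self.control_samples]
        return self.values[:, idx]


@dataclass
class GeneSetDB:
    """Flat gene-set database: (term_id, description, member set) entries."""

    entries: List[tuple]  # (term_id, description, frozenset of genes)

    def __post_init__(self) -> None:
        ids = [t for t, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate term_id in gene-set database")
        for t, _, members in self.entries:
            if not members:
                raise ValidationError(f"gene set '{t}' is empty")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def term_ids(self) -> List[str]:
        return [t for t, _, _ in self.entries]

    def members(self, term_id: str) -> frozenset:
        for t, _, m in self.entries:
            if t == term_id:
                return m
        raise KeyError(term_id)


DRUGSET_CATEGORIES = ("target", "pathway", "indication", "adverse_reaction", "other")


@dataclass
class DrugSetDB:
    """Drug-set database: (set_id, category, member drug names)."""

    entries: List[tuple]  # (set_id, category, frozenset of drug names)

    def __post_init__(self) -> None:
        ids = [t for t, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate set_id in drug-set database")
        for sid, cat, members in self.entries:
            if cat not in DRUGSET_CATEGORIES:
                raise ValidationError(f"drug set '{sid}': unknown category '{cat}'")
            if not members:
                raise ValidationError(f"drug set '{sid}' is empty")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DrugProfileCatalogue:
    """Reference catalogue of full ranked per-drug gene profiles.

    ``profiles[drug]`` is an integer array of gene indices into
    ``gene_universe``; position 0 holds the gene the drug up-regulates
    most strongly (rank 1).
    """

    gene_universe: List[str]
    profiles: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.gene_universe)
        if len(set(self.gene_universe)) != n:
            raise ValidationError("catalogue gene universe has duplicate symbols")
        full = np.arange(n)
        for drug, perm in self.profiles.items():
            perm = np.asarray(perm, dtype=int)
            self.profiles[drug] = perm
            if perm.shape != (n,) or not np.array_equal(np.sort(perm), full):
                raise ValidationError(f"profile for '{drug}' is not a permutation of the universe")

    @property
    def drugs(self) -> List[str]:
        return list(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)

    def ranks_of(self, drug: str) -> np.ndarray:
        """1-based rank of every universe gene under ``drug`` (inverse permutation)."""
        inv = np.empty(len(self.gene_universe), dtype=int)
        inv[self.profiles[drug]] = np.arange(1, len(self.gene_universe) + 1)
        return inv


# ---------------------------------------------------------------------------
# expression matrix + phenotype
# ---------------------------------------------------------------------------

def read_expression_dataset(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    metadata: Mapping[str, str],
) -> ExpressionDataset:
    """Read and validate one cohort from a matrix TSV and a phenotype TSV.

    Duplicate gene symbols are collapsed by keeping the row with the
    highest mean value; matrix sample order is preserved.
    """
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.columns[0] != "gene":
        raise ValidationError(f"{matrix_path}: first column must be named 'gene'")
    genes_raw = raw.iloc[:, 0].tolist()
    samples = [str(c) for c in raw.columns[1:]]
    body = raw.iloc[:, 1:]
    values = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{matrix_path}: non-numeric value '{body.iat[r, c]}' at gene "
            f"'{genes_raw[r]}', sample '{samples[c]}'"
        )

    # collapse accidental duplicate symbols: keep the max-mean row
    gseries = pd.Series(genes_raw)
    if gseries.duplicated().any():
        means = values.mean(axis=1)
        keep = (
            pd.DataFrame({"gene": genes_raw, "mean": means})
            .groupby("gene", sort=False)["mean"]
            .idxmax()
            .to_numpy()
        )
        keep.sort()
        dropped = len(genes_raw) - len(keep)
        logger.info("%s: collapsed %d duplicate gene rows (max-mean rule)", matrix_path, dropped)
        genes_raw = [genes_raw[i] for i in keep]
        values = values[keep]

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(pheno.columns):
        raise ValidationError(f"{phenotype_path}: need columns sample_id, group")
    group = dict(zip(pheno["sample_id"], pheno["group"]))
    for s in samples:
        if s not in group:
            raise ValidationError(f"{phenotype_path}: no phenotype for sample '{s}'")

    return ExpressionDataset(
        dataset_id=str(metadata.get("dataset_id", Path(matrix_path).stem)),
        tissue=str(metadata.get("tissue", "unknown")),
        organism=str(metadata.get("organism", "human")),
        platform_id=str(metadata.get("platform_id", "NA")),
        scale=str(metadata.get("scale", "linear")),
        genes=genes_raw,
        samples=samples,
        values=values,
        group={s: group[s] for s in samples},
    )


def write_expression_dataset(
    ds: ExpressionDataset, matrix_path: str | Path, phenotype_path: str | Path
) -> None:
    """Write a cohort back to the matrix/phenotype TSV pair, full precision."""
    df = pd.DataFrame(ds.values, columns=ds.samples)
    df.insert(0, "gene", ds.genes)
    df.to_csv(matrix_path, sep="\t", index=False, float_format="%.17g")
    pheno = pd.DataFrame({"sample_id": ds.samples, "group": [ds.group[s] for s in ds.samples]})
    pheno.to_csv(phenotype_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def _gmt_lines(path: str | Path):
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            yield lineno, line.split("\t")


def read_gmt(path: str | Path) -> GeneSetDB:
    """Read a gene-set GMT file (term, description, members...)."""
    entries = []
    seen = set()
    for lineno, fields in _gmt_lines(path):
        if len(fields) < 3:
            raise ValidationError(f"{path}:{lineno}: GMT line has < 3 fields")
        term, desc, members = fields[0], fields[1], fields[2:]
        if term in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate term_id '{term}'")
        seen.add(term)
        entries.append((term, desc, frozenset(members)))
    if not entries:
        logger.warning("%s: empty gene-set file", path)
    return GeneSetDB(entries)


def write_gmt(db: GeneSetDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, desc, members in db.entries:
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def read_drugset_gmt(path: str | Path) -> DrugSetDB:
    """Read a drug-set file in GMT layout: set_id, category, drug names..."""
    entries = []
    seen = set()
    for lineno, fields in _gmt_lines(path):
        if len(fields) < 3:
            raise ValidationError(f"{path}:{lineno}: drug-set line has < 3 fields")
        sid, cat, members = fields[0], fields[1], fields[2:]
        if sid in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate set_id '{sid}'")
        seen.add(sid)
        entries.append((sid, cat, frozenset(members)))
    if not entries:
        logger.warning("%s: empty drug-set file", path)
    return DrugSetDB(entries)


def write_drugset_gmt(db: DrugSetDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, cat, members in db.entries:
            fh.write("\t".join([sid, cat, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# drug catalogue
# ---------------------------------------------------------------------------

def read_drug_catalogue(path: str | Path) -> DrugProfileCatalogue:
    """Read the ranked-profile catalogue (drug name, then full gene order)."""
    rows: List[tuple] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: catalogue row has no genes")
            rows.append((fields[0], fields[1:]))
    if not rows:
        raise ValidationError(f"{path}: empty drug catalogue")
    universe = sorted(rows[0][1])
    index = {g: i for i, g in enumerate(universe)}
    profiles: Dict[str, np.ndarray] = {}
    for drug, genes in rows:
        if drug in profiles:
            raise ValidationError(f"{path}: duplicate drug '{drug}'")
        try:
            profiles[drug] = np.fromiter((index[g] for g in genes), dtype=int, count=len(genes))
        except KeyError as exc:
            raise ValidationError(
                f"{path}: profile for '{drug}' is not over the catalogue universe "
                f"(unknown gene {exc})"
            ) from None
    return DrugProfileCatalogue(gene_universe=universe, profiles=profiles)


def write_drug_catalogue(cat: DrugProfileCatalogue, path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug, perm in cat.profiles.items():
            genes = [cat.gene_universe[i] for i in perm]
            fh.write("\t".join([drug, *genes]) + "\n")
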