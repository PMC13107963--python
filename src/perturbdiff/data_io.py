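"""Expression-matrix and metadata I/O, cleaning filters, pairing and splits.

The cleaning pipeline mirrors a standard perturbation-screen preprocessing
order: (i) drop compounds observed fewer than ``min_count`` times among
perturbed samples in the whole dataset, (ii) drop records whose SMILES string
cannot be parsed, (iii) pair each perturbed record with its control. Filters
are idempotent and order is logged by the CLI pipeline.

Matrices are samples×genes in memory everywhere. On-disk formats are a plain
TSV (first column ``sample_id``, remaining columns gene IDs) and GCT 1.2,
which by convention stores genes as rows and is transposed on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix", "PerturbationRecord", "SplitSpec", "Pair",
    "load_expression", "write_expression", "records_from_metadata",
    "records_to_metadata", "filter_rare_compounds", "filter_invalid_smiles",
    "pair_records", "make_splits", "rdkit_smiles_validator",
    "canonical_smiles", "DataError", "PairingError", "SplitError",
]


class DataError(ValueError):
    """Malformed or contract-violating input data."""


class PairingError(DataError):
    """Ambiguous control/perturbed pairing."""


class SplitError(DataError):
    """Not enough entities to build the requested folds."""


@dataclass
class ExpressionMatrix:
    """samples × genes continuous expression values with identifiers."""

    values: np.ndarray
    sample_ids: List[str]
    gene_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D samples×genes array")
        n, g = self.values.shape
        if n != len(self.sample_ids) or g != len(self.gene_ids):
            raise DataError(
                f"shape {self.values.shape} does not match {len(self.sample_ids)} "
                f"sample ids × {len(self.gene_ids)} gene ids")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample_ids must be unique")
        if len(set(self.gene_ids)) != g:
            raise DataError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return ExpressionMatrix(self.values[rows], list(sample_ids), list(self.gene_ids))


def load_expression(path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        if df.isna().any().any():
            bad = int(df.isna().any(axis=1).to_numpy().argmax()) + 2  # header line 1
            raise DataError(f"{path}: missing values (first bad data line {bad})")
        mat = ExpressionMatrix.from_dataframe(df)
    elif format == "gct":
        mat = _load_gct(path)
    else:
        raise DataError(f"unknown expression format {format!r}")
    logger.info("loaded %s: %d samples × %d genes", path, mat.n_samples, mat.n_genes)
    return mat


def write_expression(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    if format == "tsv":
        df = matrix.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "gct":
        _write_gct(matrix, path)
    else:
        raise DataError(f"unknown expression format {format!r}")


def _load_gct(path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "#1.2":
            raise DataError(f"{path}: line 1 is {header!r}, expected '#1.2'")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise DataError(f"{path}: line 2 must hold two dimensions")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if body.shape[0] != n_genes or body.shape[1] - 2 != n_samples:
        raise DataError(
            f"{path}: dimension line says {n_genes}×{n_samples}, body is "
            f"{body.shape[0]}×{body.shape[1] - 2}")
    genes = body.iloc[:, 0].astype(str).tolist()
    values = body.iloc[:, 2:].to_numpy(dtype=float).T  # -> samples×genes
    return ExpressionMatrix(values, list(body.columns[2:]), genes)


def _write_gct(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for gi, gene in enumerate(matrix.gene_ids):
            row = "\t".join(f"{v:.17g}" for v in matrix.values[:, gi])
            fh.write(f"{gene}\t{gene}\t{row}\n")


# ---------------------------------------------------------------------------
# metadata records


@dataclass(frozen=True)
class PerturbationRecord:
    """Per-sample condition metadata; controls carry dose 0 and empty SMILES."""

    sample_id: str
    pair_id: str
    cell_line: str
    smiles: str
    dose: float     # µM
    time: float     # h
    role: str       # "control" | "perturbed"

    def __post_init__(self) -> None:
        if self.role not in ("control", "perturbed"):
            raise DataError(f"{self.sample_id}: role must be control|perturbed")
        if self.role == "perturbed" and not self.dose > 0:
            raise DataError(f"{self.sample_id}: perturbed record needs dose > 0")
        if self.role == "perturbed" and not self.time > 0:
            raise DataError(f"{self.sample_id}: perturbed record needs time > 0")


def records_from_metadata(meta: pd.DataFrame) -> List[PerturbationRecord]:
    required = {"sample_id", "pair_id", "cell_line", "smiles", "dose_um",
                "time_h", "role"}
    missing = required - set(meta.columns)
    if missing:
        raise DataError(f"metadata is missing columns {sorted(missing)}")
    records = [
        PerturbationRecord(
            sample_id=str(r.sample_id), pair_id=str(r.pair_id),
            cell_line=str(r.cell_line),
            smiles="" if pd.isna(r.smiles) else str(r.smiles),
            dose=float(r.dose_um), time=float(r.time_h), role=str(r.role))
        for r in meta.itertuples(index=False)
    ]
    if len({r.sample_id for r in records}) != len(records):
        raise DataError("duplicate sample_id in metadata")
    return records


def records_to_metadata(records: Iterable[PerturbationRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(sample_id=r.sample_id, pair_id=r.pair_id, cell_line=r.cell_line,
             smiles=r.smiles, dose_um=r.dose, time_h=r.time, role=r.role)
        for r in records])


def canonical_smiles(smiles: str) -> Optional[str]:
    """RDKit-canonicalized SMILES, or None if unparsable."""
    try:
        from rdkit import Chem
        from rdkit import RDLogger
        RDLogger.DisableLog("rdApp.error")
    except ImportError:   # pragma: no cover - rdkit is a hard dependency
        return smiles
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def rdkit_smiles_validator(smiles: str) -> bool:
    return canonical_smiles(smiles) is not None


def filter_rare_compounds(records: Sequence[PerturbationRecord],
                          min_count: int = 5) -> List[PerturbationRecord]:
    """Drop perturbed records of compounds seen fewer than ``min_count`` times.

    Counting is over perturbed records in the entire input, keyed by
    canonical SMILES when parsable (falling back to the raw string), so that
    the same molecule written two ways is counted once. A compound seen
    exactly ``min_count`` times is kept. Controls always pass. Order preserved.
    """
    keys = {}
    counts: dict = {}
    for r in records:
        if r.role != "perturbed":
            continue
        key = canonical_smiles(r.smiles) or r.smiles
        keys[r.sample_id] = key
        counts[key] = counts.get(key, 0) + 1
    kept = [r for r in records
            if r.role != "perturbed" or counts[keys[r.sample_id]] >= min_count]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_rare_compounds: removed %d records (min_count=%d)",
                    removed, min_count)
    return kept


def filter_invalid_smiles(records: Sequence[PerturbationRecord],
                          validator: Callable[[str], bool] = rdkit_smiles_validator,
                          ) -> List[PerturbationRecord]:
    """Drop perturbed records whose SMILES fails ``validator``."""
    kept, dropped = [], []
    for r in records:
        if r.role != "perturbed":
            kept.append(r)
            continue
        try:
            ok = bool(validator(r.smiles))
        except Exception as exc:
            raise DataError(
                f"SMILES validator failed on record {r.sample_id!r} "
                f"({r.smiles!r}): {exc}") from exc
        if ok:
            kept.append(r)
        else:
            dropped.append(r)
    for r in dropped:
        logger.info("filter_invalid_smiles: removed %s (smiles=%r)",
                    r.sample_id, r.smiles)
    return kept


@dataclass(frozen=True)
class Pair:
    control_id: str
    perturbed_id: str
    cell_line: str
    smiles: str
    dose: float
    time: float


def pair_records(records: Sequence[PerturbationRecord]) -> List[Pair]:
    """One pair per perturbed record, resolved through its pair_id.

    A pair_id resolving to more than one control is an error; a perturbed
    record whose pair_id matches no control (or a control of a different cell
    line) is dropped with a log entry.
    """
    controls: dict = {}
    for r in records:
        if r.role == "control":
            if r.pair_id in controls:
                raise PairingError(f"pair_id {r.pair_id!r} matches >1 control")
            controls[r.pair_id] = r
    pairs, dropped = [], 0
    for r in records:
        if r.role != "perturbed":
            continue
        ctrl = controls.get(r.pair_id)
        if ctrl is None or ctrl.cell_line != r.cell_line:
            dropped += 1
            continue
        pairs.append(Pair(ctrl.sample_id, r.sample_id, r.cell_line, r.smiles,
                          r.dose, r.time))
    if dropped:
        logger.info("pair_records: dropped %d unpairable perturbed records", dropped)
    return pairs


@dataclass(frozen=True)
class SplitSpec:
    mode: str = "unseen_compound"   # unseen_compound | unseen_cell_line | random
    n_folds: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("unseen_compound", "unseen_cell_line", "random"):
            raise DataError(f"unknown split mode {self.mode!r}")
        if self.n_folds < 2:
            raise DataError("n_folds must be >= 2")


def _entity_of(record: PerturbationRecord, mode: str) -> str:
    if mode == "unseen_compound":
        return canonical_smiles(record.smiles) or record.smiles
    if mode == "unseen_cell_line":
        return record.cell_line
    return record.sample_id


def make_splits(records: Sequence[PerturbationRecord], spec: SplitSpec,
                ) -> List[Tuple[List[PerturbationRecord], List[PerturbationRecord]]]:
    """Cross-validation folds over perturbed records.

    In the unseen-entity modes the compound (or cell-line) set is partitioned
    into ``n_folds`` disjoint subsets; a fold's test set holds the perturbed
    records of its entities and its train set the rest. Control records are
    carried into every fold's train set (they are conditioning inputs, not
    prediction targets). Deterministic under ``spec.seed``.
    """
    perturbed = [r for r in records if r.role == "perturbed"]
    controls = [r for r in records if r.role == "control"]
    entities = sorted({_entity_of(r, spec.mode) for r in perturbed})
    if len(entities) < spec.n_folds:
        raise SplitError(
            f"need >= {spec.n_folds} distinct entities for mode {spec.mode}, "
            f"have {len(entities)}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(entities))
    assignment = {entities[j]: i % spec.n_folds for i, j in enumerate(order)}
    folds = []
    for fold in range(spec.n_folds):
        test = [r for r in perturbed if assignment[_entity_of(r, spec.mode)] == fold]
        train = [r for r in perturbed if assignment[_entity_of(r, spec.mode)] != fold]
        folds.append((controls + train, test))
    return folds
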