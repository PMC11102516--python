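"""Domain types and CSV readers/writers for all tabular inputs and outputs.

Dialect: comma-delimited UTF-8 with a required header row, ``.`` decimal
separator; ``NA`` and the empty string denote missing values (the convention
of public screening-portal exports). Expression matrices are cell lines x genes; a transpose flag covers
genes x cells files. Gene-target sets are serialized ``;``-joined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


class FormatError(ValueError):
    """A table does not conform to the documented CSV dialect."""


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed by the cheminformatics backend."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseRecord:
    """One screened drug-cell line pair's fitted dose-response parameters.

    ``auc`` is the area under the viability curve (lower = more sensitive),
    ``lower_limit`` the minimum attainable viability fraction, ``ic50`` the
    half-maximal inhibitory concentration in dataset-native units, and ``r2``
    the curve-fit quality. Unparseable numerics are stored as ``None``
    (missing), never coerced to zero.
    """

    drug_id: str
    cell_id: str
    auc: Optional[float]
    lower_limit: Optional[float]
    ic50: Optional[float]
    r2: Optional[float]
    screen_id: str = ""

    def has_missing_values(self) -> bool:
        return any(v is None for v in (self.auc, self.lower_limit, self.ic50))


@dataclass
class DrugProfile:
    """A drug's raw feature vector (Morgan fingerprint) plus grouping metadata."""

    drug_id: str
    smiles: Optional[str] = None
    fingerprint: Optional[np.ndarray] = None  # uint8 0/1 vector
    gene_targets: frozenset = frozenset()
    moa: Optional[str] = None
    withdrawn: bool = False

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint, dtype=np.uint8)
            if not np.isin(fp, (0, 1)).all():
                raise ValueError(f"fingerprint of {self.drug_id} has non-binary bits")
            self.fingerprint = fp
        self.gene_targets = frozenset(self.gene_targets)


@dataclass
class CellLineProfile:
    """A cell line's cancer-type label and log-scale expression vector over the gene panel."""

    cell_id: str
    cancer_type: str = ""
    expression: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.expression is not None:
            self.expression = np.asarray(self.expression, dtype=float)


@dataclass
class CDRPair:
    """A scored, labeled drug-cell line pair (continuous effective score + 0/1 label)."""

    drug_id: str
    cell_id: str
    ces: float
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not math.isfinite(self.ces):
            raise ValueError(f"CES must be finite, got {self.ces!r}")


@dataclass
class EmbeddingSet:
    """Learned vectors for drugs or cell lines, keyed by entity id."""

    entity_kind: str  # "drug" | "cell"
    ids: list
    vectors: np.ndarray  # (n entities, embedding dim)

    def __post_init__(self) -> None:
        if self.entity_kind not in ("drug", "cell"):
            raise ValueError(f"entity_kind must be 'drug' or 'cell', got {self.entity_kind!r}")
        self.ids = list(self.ids)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be a matrix with one row per id")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate entity ids in EmbeddingSet")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite values in embedding matrix")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, entity_id: str) -> np.ndarray:
        return self.vectors[self.ids.index(entity_id)]

    def as_dict(self) -> dict:
        return {i: self.vectors[k] for k, i in enumerate(self.ids)}

    def to_csv(self, path) -> None:
        cols = [f"dim_{j}" for j in range(self.dim)]
        df = pd.DataFrame(self.vectors, columns=cols)
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, entity_kind: str) -> "EmbeddingSet":
        df = pd.read_csv(path)
        if "id" not in df.columns:
            raise FormatError("embedding CSV lacks required column 'id'")
        dims = [c for c in df.columns if c.startswith("dim_")]
        return cls(entity_kind, df["id"].astype(str).tolist(), df[dims].to_numpy(float))


@dataclass
class PrioritizationResult:
    """A per-cell ranked drug list: (drug_id, predicted score, rank) triples.

    Scores are non-increasing with rank; ranks run 1..n without gaps; exact
    score ties are broken by ascending drug id so the order is deterministic.
    """

    cell_id: str
    ranked_drugs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        prev = math.inf
        for i, (drug_id, score, rank) in enumerate(self.ranked_drugs, start=1):
            if rank != i:
                raise ValueError(f"ranks must be 1..n with no gaps, got {rank} at position {i}")
            if score > prev + 1e-15:
                raise ValueError("scores must be non-increasing with rank")
            prev = score

    def top_k(self, k: int) -> list:
        return [d for d, _, _ in self.ranked_drugs[:k]]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_DOSE_COLUMNS = ("drug_id", "cell_id", "auc", "lower_limit", "ic50", "r2", "screen_id")


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc
    return df


def _parse_float(token: str) -> Optional[float]:
    if token.strip() in MISSING_TOKENS:
        return None
    try:
        value = float(token)
    except ValueError:
        return None
    return value if math.isfinite(value) else None


def read_dose_response(path) -> list:
    """Read a dose-response parameter table into :class:`DoseResponseRecord` rows.

    Extra columns are ignored; unparseable numeric cells become missing flags.
    Raises :class:`FormatError` if a required column is absent or the
    (drug, cell, screen) triple is duplicated.
    """
    df = _read_csv(path)
    for col in _DOSE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"dose-response table lacks required column '{col}'")
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        rec = DoseResponseRecord(
            drug_id=str(getattr(row, "drug_id")),
            cell_id=str(getattr(row, "cell_id")),
            auc=_parse_float(getattr(row, "auc")),
            lower_limit=_parse_float(getattr(row, "lower_limit")),
            ic50=_parse_float(getattr(row, "ic50")),
            r2=_parse_float(getattr(row, "r2")),
            screen_id=str(getattr(row, "screen_id")),
        )
        key = (rec.drug_id, rec.cell_id, rec.screen_id)
        if key in seen:
            raise FormatError(f"duplicate (drug, cell, screen) triple {key}")
        seen.add(key)
        records.append(rec)
    return records


def read_drug_metadata(path, n_bits: int = 256, radius: int = 3,
                       compute_fingerprints: bool = False) -> list:
    """Read drug metadata (id, SMILES, MOA, ;-joined gene targets, withdrawn flag).

    An optional ``fingerprint`` column holds the bit vector as a 0/1 string;
    otherwise fingerprints are computed from SMILES when
    ``compute_fingerprints`` is set.
    """
    df = _read_csv(path)
    if "drug_id" not in df.columns:
        raise FormatError("drug metadata lacks required column 'drug_id'")
    drugs = []
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        smiles = rowd.get("smiles", "") or None
        targets = frozenset(t for t in rowd.get("gene_targets", "").split(";") if t)
        fingerprint = None
        fp_str = rowd.get("fingerprint", "")
        if fp_str:
            fingerprint = np.frombuffer(fp_str.encode(), dtype=np.uint8) - ord("0")
        elif compute_fingerprints and smiles:
            fingerprint = fingerprint_drug(smiles, n_bits=n_bits, radius=radius)
        drugs.append(DrugProfile(
            drug_id=str(rowd["drug_id"]),
            smiles=smiles,
            fingerprint=fingerprint,
            gene_targets=targets,
            moa=rowd.get("moa", "") or None,
            withdrawn=str(rowd.get("withdrawn", "")).strip().lower() in ("1", "true", "yes"),
        ))
    if len({d.drug_id for d in drugs}) != len(drugs):
        raise FormatError("duplicate drug_id rows in drug metadata")
    return drugs


def read_cell_metadata(path) -> dict:
    """Read cell-line metadata; returns a cell_id -> cancer_type mapping."""
    df = _read_csv(path)
    for col in ("cell_id", "cancer_type"):
        if col not in df.columns:
            raise FormatError(f"cell metadata lacks required column '{col}'")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise FormatError(f"duplicate cell_id rows in cell metadata: {dup}")
    return dict(zip(df["cell_id"].astype(str), df["cancer_type"].astype(str)))


def read_gene_panel(path) -> list:
    """Read a gene panel: one gene symbol per line, blanks ignored."""
    with open(path, encoding="utf-8") as fh:
        panel = [line.strip() for line in fh if line.strip()]
    if not panel:
        raise FormatError(f"gene panel is empty: {path}")
    return panel


def read_expression(path, gene_panel: Sequence[str], transpose: bool = False) -> list:
    """Read an expression matrix restricted to ``gene_panel``, in panel order.

    Rows are cell lines and columns genes (pass ``transpose=True`` for a
    genes x cells file). The first column is the cell id. A panel gene absent
    from the file, or a duplicated cell id, is an error; cancer types are not
    carried here (join with :func:`read_cell_metadata`).
    """
    df = _read_csv(path)
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(names="cell_id")
    id_col = df.columns[0]
    for gene in gene_panel:
        if gene not in df.columns:
            raise FormatError(f"panel gene '{gene}' absent from expression matrix")
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        raise FormatError(f"duplicate cell id rows: {ids[ids.duplicated()].iloc[0]}")
    values = df[list(gene_panel)].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if not np.isfinite(values).all():
        bad = ids.iloc[int(np.argwhere(~np.isfinite(values))[0][0])]
        raise FormatError(f"cell '{bad}' is missing a panel gene value")
    return [CellLineProfile(cell_id=i, expression=v) for i, v in zip(ids, values)]


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def fingerprint_drug(smiles: str, n_bits: int = 256, radius: int = 3) -> np.ndarray:
    """Hashed circular-substructure (Morgan/ECFP-style) fingerprint of a molecule.

    Deterministic for a given SMILES; the bit order is the rdkit Morgan
    generator convention. Defaults follow the screening-pipeline convention of
    256 bits at radius 3.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_prioritization(result: PrioritizationResult, path) -> None:
    """Write a ranked drug list as CSV (cell_id, rank, drug_id, score)."""
    df = pd.DataFrame(
        [(result.cell_id, rank, drug_id, score) for drug_id, score, rank in result.ranked_drugs],
        columns=["cell_id", "rank", "drug_id", "score"],
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_prioritization(path) -> list:
    """Read one or more prioritizations written by :func:`write_prioritization`."""
    df = _read_csv(path)
    for col in ("cell_id", "rank", "drug_id", "score"):
        if col not in df.columns:
            raise FormatError(f"prioritization CSV lacks required column '{col}'")
    results = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("rank", key=lambda s: s.astype(int))
        ranked = [(str(r.drug_id), float(r.score), int(r.rank)) for r in grp.itertuples()]
        results.append(PrioritizationResult(cell_id=str(cell_id), ranked_drugs=ranked))
    return results


def write_dose_response(records: Iterable[DoseResponseRecord], path) -> None:
    def fmt(v):
        return "NA" if v is None else repr(float(v))

    df = pd.DataFrame(
        [(r.drug_id, r.cell_id, fmt(r.auc), fmt(r.lower_limit), fmt(r.ic50), fmt(r.r2), r.screen_id)
         for r in records],
        columns=list(_DOSE_COLUMNS),
    )
    df.to_csv(path, index=False)


def write_drug_metadata(drugs: Iterable[DrugProfile], path) -> None:
    rows = []
    for d in drugs:
        fp = "" if d.fingerprint is None else "".join(map(str, d.fingerprint.tolist()))
        rows.append((d.drug_id, d.smiles or "", d.moa or "",
                     ";".join(sorted(d.gene_targets)), int(d.withdrawn), fp))
    pd.DataFrame(rows, columns=["drug_id", "smiles", "moa", "gene_targets", "withdrawn",
                                "fingerprint"]).to_csv(path, index=False)


def write_cell_metadata(cells: Iterable[CellLineProfile], path) -> None:
    pd.DataFrame([(c.cell_id, c.cancer_type) for c in cells],
                 columns=["cell_id", "cancer_type"]).to_csv(path, index=False)


def write_expression(cells: Iterable[CellLineProfile], gene_panel: Sequence[str], path) -> None:
    cells = list(cells)
    df = pd.DataFrame(np.vstack([c.expression for c in cells]), columns=list(gene_panel))
    df.insert(0, "cell_id", [c.cell_id for c in cells])
    df.to_csv(path, index=False, float_format="%.12g")


def write_gene_panel(gene_panel: Sequence[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(gene_panel) + "\n")
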