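"""Dataset container, validation, persistence and run configuration.

A dataset directory follows the layout of the public DTINet matrix
collection: whitespace-delimited dense numeric text, one matrix row per
line, plus one-identifier-per-line id files.  The drug-target interaction
matrix ``Y`` is binary (1 = known interaction); the association matrices
link drugs/targets to diseases and side effects; the two precomputed
similarity matrices come from chemical structure (drugs) and amino-acid
sequence (targets).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "DtiDataset",
    "RunConfig",
    "load_dataset",
    "save_dataset",
    "validate_dataset",
    "count_known_entities",
    "FILE_LAYOUT",
]

# file name -> DtiDataset field, matching the public dataset's layout
FILE_LAYOUT = {
    "drug.txt": "drug_ids",
    "protein.txt": "target_ids",
    "mat_drug_protein.txt": "Y",
    "mat_drug_drug.txt": "A_drug",
    "mat_protein_protein.txt": "A_target",
    "mat_drug_disease.txt": "B_drug_disease",
    "mat_drug_se.txt": "B_drug_sideeffect",
    "mat_protein_disease.txt": "B_target_disease",
    "Similarity_Matrix_Drugs.txt": "S_chemical",
    "Similarity_Matrix_Proteins.txt": "S_sequence",
}

_BINARY_FIELDS = ("Y", "A_drug", "A_target", "B_drug_disease",
                  "B_drug_sideeffect", "B_target_disease")
_SIMILARITY_FIELDS = ("S_chemical", "S_sequence")


@dataclass
class DtiDataset:
    """The full matrix collection one prediction run consumes.

    ``m`` drugs and ``n`` targets; ``Y`` is the m-by-n binary interaction
    matrix, ``A_*`` the intra-type interaction networks, ``B_*`` the
    binary association matrices and ``S_*`` the precomputed real-valued
    similarity matrices with unit diagonal.
    """

    drug_ids: list
    target_ids: list
    Y: np.ndarray
    A_drug: np.ndarray
    A_target: np.ndarray
    B_drug_disease: np.ndarray
    B_drug_sideeffect: np.ndarray
    B_target_disease: np.ndarray
    S_chemical: np.ndarray
    S_sequence: np.ndarray

    @property
    def m(self) -> int:
        return self.Y.shape[0]

    @property
    def n(self) -> int:
        return self.Y.shape[1]

    def copy(self) -> "DtiDataset":
        kw = {}
        for f in dataclasses.fields(DtiDataset):
            v = getattr(self, f.name)
            kw[f.name] = v.copy() if isinstance(v, np.ndarray) else list(v)
        return DtiDataset(**kw)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DtiDataset):
            return NotImplemented
        for f in dataclasses.fields(DtiDataset):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, np.ndarray):
                if a.shape != b.shape or not np.array_equal(a, b):
                    return False
            elif list(a) != list(b):
                return False
        return True


@dataclass
class RunConfig:
    """Hyperparameters of a full run; defaults are the published settings.

    ``eta`` and ``K`` drive the weighted K-nearest-known-neighbour
    densification, ``p`` the mutual-nearest-neighbour graph of the spatial
    consistency constraint, the three lambdas weight its Tikhonov and
    Laplacian terms.  ``hidden_dim``/``embed_dim`` are the two GCN layer
    widths (l and k).  The ablation flags switch off densification
    (``use_ddm``), the spatial constraint (``use_scc``) and the adversarial
    regularizer (``use_gan``).
    """

    eta: float = 0.8
    K: int = 10
    p: int = 5
    lambda_l: float = 1e-5
    lambda_d: float = 1e-3
    lambda_t: float = 1e-3
    hidden_dim: int = 500
    embed_dim: int = 200
    epochs: int = 5000
    lr_repr: float = 1e-4
    lr_gbdt: float = 0.02
    n_estimators: int = 500
    num_leaves: int = 31
    n_folds: int = 10
    seed: int = 0
    use_ddm: bool = True
    use_scc: bool = True
    use_gan: bool = True
    # side knobs exposed by design decisions
    wknkn_agg: str = "mean"        # "mean" or "max" of drug/target-side estimates
    features: str = "similarity"   # node features: "similarity" blocks or "adjacency"
    scc_trace_factor: float = 2.0  # trace-form constant matching the double-sum loss

    def __post_init__(self):
        if not (0.0 < self.eta <= 1.0):
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")
        if self.K < 1 or self.p < 1:
            raise ValueError("K and p must be >= 1")
        for name in ("lambda_l", "lambda_d", "lambda_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.wknkn_agg not in ("mean", "max"):
            raise ValueError("wknkn_agg must be 'mean' or 'max'")

    @classmethod
    def desk_profile(cls, **overrides) -> "RunConfig":
        """Small-dimension profile for minutes-scale runs on desk hardware."""
        base = dict(hidden_dim=64, embed_dim=32, epochs=400,
                    lr_repr=5e-3, n_estimators=300)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def _read_matrix(path: Path) -> np.ndarray:
    arr = np.loadtxt(path, dtype=np.float64, ndmin=2)
    return arr


def _read_ids(path: Path) -> list:
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def load_dataset(directory) -> DtiDataset:
    """Load a dataset directory and cross-check all matrix dimensions.

    Raises ``FileNotFoundError`` naming the first missing file and
    ``ValueError`` on dimension mismatches or non-binary entries in a
    binary matrix (with coordinates).
    """
    directory = Path(directory)
    fields = {}
    for fname, attr in FILE_LAYOUT.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"dataset file missing: {path}")
        fields[attr] = _read_ids(path) if attr.endswith("_ids") else _read_matrix(path)
    ds = DtiDataset(**fields)
    _check_dimensions(ds)
    violations = validate_dataset(ds)
    if violations:
        raise ValueError("dataset validation failed:\n" + "\n".join(violations))
    return ds


def save_dataset(ds: DtiDataset, directory) -> None:
    """Write a dataset directory in the canonical text layout (lossless)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for fname, attr in FILE_LAYOUT.items():
        v = getattr(ds, attr)
        path = directory / fname
        if attr.endswith("_ids"):
            path.write_text("".join(f"{x}\n" for x in v))
        else:
            np.savetxt(path, np.asarray(v, dtype=np.float64), fmt="%.17g")


def _check_dimensions(ds: DtiDataset) -> None:
    m, n = ds.Y.shape
    expected = {
        "A_drug": (m, m), "A_target": (n, n),
        "S_chemical": (m, m), "S_sequence": (n, n),
    }
    for attr, shape in expected.items():
        got = getattr(ds, attr).shape
        if got != shape:
            raise ValueError(f"dimension mismatch: {attr} is {got}, "
                             f"expected {shape} from Y {ds.Y.shape}")
    for attr, axis_len in (("B_drug_disease", m), ("B_drug_sideeffect", m),
                           ("B_target_disease", n)):
        got = getattr(ds, attr).shape
        if got[0] != axis_len:
            raise ValueError(f"dimension mismatch: {attr} has {got[0]} rows, "
                             f"expected {axis_len} from Y {ds.Y.shape}")
    if len(ds.drug_ids) != m:
        raise ValueError(f"dimension mismatch: {len(ds.drug_ids)} drug ids vs Y rows {m}")
    if len(ds.target_ids) != n:
        raise ValueError(f"dimension mismatch: {len(ds.target_ids)} target ids "
                         f"vs Y columns {n}")
    d1, d2 = ds.B_drug_disease.shape[1], ds.B_target_disease.shape[1]
    if d1 != d2:
        raise ValueError(f"dimension mismatch: B_drug_disease has {d1} diseases, "
                         f"B_target_disease has {d2}")


def validate_dataset(ds: DtiDataset) -> list[str]:
    """Return a list of invariant-violation descriptions (empty iff valid)."""
    out: list[str] = []
    for attr in _BINARY_FIELDS:
        M = getattr(ds, attr)
        bad = np.argwhere((M != 0) & (M != 1))
        if bad.size:
            i, j = bad[0]
            out.append(f"{attr}: non-binary entry {M[i, j]!r} at ({i}, {j})")
    for attr in ("A_drug", "A_target"):
        M = getattr(ds, attr)
        if not np.array_equal(M, M.T):
            out.append(f"{attr}: not symmetric")
        if np.any(np.diag(M) != 0):
            out.append(f"{attr}: nonzero diagonal")
    for attr in _SIMILARITY_FIELDS:
        S = getattr(ds, attr)
        if not np.allclose(S, S.T, atol=1e-12):
            out.append(f"{attr}: not symmetric")
        if not np.allclose(np.diag(S), 1.0, atol=1e-12):
            out.append(f"{attr}: diagonal not all 1")
        if S.min() < -1e-12 or S.max() > 1 + 1e-12:
            out.append(f"{attr}: entries outside [0, 1] "
                       f"(min {S.min():.3g}, max {S.max():.3g})")
    return out


def count_known_entities(ds: DtiDataset) -> tuple[int, int, int, int]:
    """Count (known_drugs, unknown_drugs, known_targets, unknown_targets).

    Unknown drugs/targets have no known interaction at all, i.e. an
    all-zero row/column of Y; they are isolated nodes in the interaction
    network.
    """
    unknown_drugs = int(np.sum(ds.Y.sum(axis=1) == 0))
    unknown_targets = int(np.sum(ds.Y.sum(axis=0) == 0))
    return (ds.m - unknown_drugs, unknown_drugs,
            ds.n - unknown_targets, unknown_targets)
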