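"""Structural connectomes: loading, validation, and synthetic generation.

The network dynamics are constrained by a weighted, non-negative N x N
structural connectivity matrix (streamline-count-like units).  Raw weights
are stored untouched; normalisation (division by the global maximum) is the
dynamics module's job, so a loaded matrix stays faithful to its source file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "load_connectome",
    "write_connectome",
    "generate_synthetic_connectome",
]


def _default_labels(n_nodes: int) -> list[str]:
    """Stable node identifiers: first half left ("L01".."Lkk"), rest right."""
    half = n_nodes // 2
    left = [f"L{i + 1:02d}" for i in range(half)]
    right = [f"R{i + 1:02d}" for i in range(n_nodes - half)]
    return left + right


@dataclass(frozen=True)
class Connectome:
    """A weighted, non-negative structural connectivity matrix.

    Parameters
    ----------
    weights
        N x N array of non-negative connection strengths with a zero
        diagonal (no self-coupling).
    labels
        N node identifiers.
    hemisphere
        N tags, each ``"left"`` or ``"right"``.
    """

    weights: np.ndarray
    labels: list[str] = field(default=None)  # type: ignore[assignment]
    hemisphere: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got shape {w.shape}")
        if np.any(w < 0):
            raise ValueError("connectivity weights must be non-negative")
        if np.any(np.diag(w) != 0):
            logger.warning("nonzero diagonal in connectivity matrix; forcing to 0")
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)
        n = w.shape[0]
        labels = self.labels if self.labels is not None else _default_labels(n)
        if len(labels) != n:
            raise ValueError(f"expected {n} labels, got {len(labels)}")
        object.__setattr__(self, "labels", list(labels))
        hemi = self.hemisphere
        if hemi is None:
            hemi = ["left" if lab.upper().startswith("L") else "right" for lab in labels]
        if len(hemi) != n:
            raise ValueError(f"expected {n} hemisphere tags, got {len(hemi)}")
        bad = set(hemi) - {"left", "right"}
        if bad:
            raise ValueError(f"hemisphere tags must be 'left'/'right', got {bad}")
        object.__setattr__(self, "hemisphere", list(hemi))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def mirror_index(self, i: int) -> int:
        """Index of the homologous node in the opposite hemisphere.

        Defined for the default bilateral layout (first half left, second
        half right, pairs aligned by position).
        """
        half = self.n_nodes // 2
        return i + half if i < half else i - half


def load_connectome(path: str | Path, delimiter: str = ",") -> Connectome:
    """Load a connectivity matrix from a delimited text file.

    The file may be a bare numeric matrix, or carry a header row and a
    first column of node labels (both together).  Negative entries and
    non-square shapes are rejected; a nonzero diagonal is forced to zero
    with a logged warning.
    """
    path = Path(path)
    try:
        first = path.open("r", encoding="utf-8").readline()
    except OSError as exc:
        raise IOError(f"cannot read connectome file {path}: {exc}") from exc

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    tokens = [t for t in first.strip().split(delimiter) if t != ""]
    has_header = not all(_is_number(t) for t in tokens)
    if has_header:
        df = pd.read_csv(path, sep=delimiter, header=0, index_col=0,
                         float_precision="round_trip")
        labels = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        df = pd.read_csv(path, sep=delimiter, header=None,
                         float_precision="round_trip")
        labels = None
        values = df.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(
            f"connectome file {path} is not a square matrix (shape {values.shape})"
        )
    return Connectome(weights=values, labels=labels)


def write_connectome(c: Connectome, path: str | Path) -> None:
    """Write a connectome as CSV with a label header row and label column.

    Weights are printed with 17 significant digits so that a
    load/write/load cycle reproduces them exactly.
    """
    path = Path(path)
    df = pd.DataFrame(c.weights, index=c.labels, columns=c.labels)
    try:
        df.to_csv(path, float_format="%.17g")
    except OSError as exc:
        raise IOError(f"cannot write connectome file {path}: {exc}") from exc


def generate_synthetic_connectome(
    n_nodes: int = 66,
    n_modules: int = 4,
    intra_density: float = 0.3,
    inter_density: float = 0.05,
    weight_scale: float = 1.0,
    seed: int = 0,
) -> Connectome:
    """Generate a bilateral, modular, heavy-tailed synthetic connectome.

    Emulates the gross statistics of a streamline-count structural matrix:
    two hemispheres of ``n_nodes / 2`` regions, ``n_modules`` modules per
    hemisphere with denser intra-module connectivity, homologous mirror
    pairs always connected, log-normal positive weights, symmetric with a
    zero diagonal.  No anatomical fidelity is claimed.

    Parameters
    ----------
    n_nodes
        Total number of regions (must be even; default 66).
    n_modules
        Modules per hemisphere.
    intra_density
        Connection probability within a module, in (0, 1].
    inter_density
        Connection probability between modules, in (0, 1]; must not exceed
        ``intra_density``.
    weight_scale
        Multiplicative scale of the log-normal weights.
    seed
        Seed for the dedicated random stream; identical seeds give
        bit-identical matrices.
    """
    if n_nodes <= 0 or n_nodes % 2 != 0:
        raise ValueError(f"n_nodes must be even and positive, got {n_nodes}")
    if n_modules <= 0:
        raise ValueError(f"n_modules must be positive, got {n_modules}")
    for name, d in (("intra_density", intra_density), ("inter_density", inter_density)):
        if not (0 < d <= 1):
            raise ValueError(f"{name} must be in (0, 1], got {d}")
    if inter_density > intra_density:
        raise ValueError("inter_density must not exceed intra_density")
    if weight_scale <= 0:
        raise ValueError(f"weight_scale must be positive, got {weight_scale}")

    rng = np.random.default_rng(seed)
    half = n_nodes // 2
    # module id per node; mirrored across hemispheres
    module = np.empty(n_nodes, dtype=int)
    module[:half] = np.arange(half) * n_modules // half
    module[half:] = module[:half]

    same_hemi = np.zeros((n_nodes, n_nodes), dtype=bool)
    same_hemi[:half, :half] = True
    same_hemi[half:, half:] = True
    same_module = module[:, None] == module[None, :]

    density = np.where(same_module & same_hemi, intra_density, inter_density)
    iu = np.triu_indices(n_nodes, k=1)
    present = rng.random(len(iu[0])) < density[iu]
    w_upper = np.where(present, rng.lognormal(0.0, 1.0, len(iu[0])) * weight_scale, 0.0)

    weights = np.zeros((n_nodes, n_nodes))
    weights[iu] = w_upper
    weights = weights + weights.T
    # homologous mirror pairs are always connected
    mirror_w = rng.lognormal(0.0, 1.0, half) * weight_scale
    for i in range(half):
        j = i + half
        if weights[i, j] == 0:
            weights[i, j] = weights[j, i] = mirror_w[i]
    np.fill_diagonal(weights, 0.0)
    return Connectome(weights=weights)
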