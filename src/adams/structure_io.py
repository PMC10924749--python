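"""Structure parsing and distance-matrix imaging.

A protein chain is reduced to the ordered 3D coordinates of its Calpha
backbone atoms. The all-versus-all Euclidean distance matrix of that trace
is invariant to rigid-body motion and is rendered as an 8-bit grayscale
image for downstream keypoint extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import (
    ChainNotFoundError,
    EmptyTraceError,
    FormatError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CalphaTrace",
    "DistanceImage",
    "load_calpha_trace",
    "compute_distance_matrix",
    "normalize_matrix",
    "write_matrix_tsv",
    "write_image_png",
]


@dataclass
class CalphaTrace:
    """Ordered Calpha coordinates of one chain.

    Attributes
    ----------
    id : str
        Structure identifier (by default the source file stem).
    coords : numpy.ndarray
        Shape ``(length, 3)`` float64 array of positions in angstrom, one
        row per residue with an observed Calpha, in record order.
    """

    id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidInputError(
                f"coords must be (n, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise EmptyTraceError("trace must contain at least one Calpha")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidInputError("coords contain non-finite values")

    @property
    def length(self) -> int:
        return self.coords.shape[0]


@dataclass
class DistanceImage:
    """Pairwise Calpha distance matrix and its 8-bit image rendering.

    ``D`` holds distances in angstrom; ``img`` is the 0-255 normalized
    integer image (``None`` until :func:`normalize_matrix` is applied).
    """

    id: str
    D: np.ndarray
    img: np.ndarray | None = field(default=None)


def _best_calpha(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy carbon CA atom of a residue (ties: first seen)."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element.name != "C":
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def load_calpha_trace(
    path: str | Path,
    chain: str | None = None,
    structure_id: str | None = None,
) -> CalphaTrace:
    """Extract the Calpha trace of one chain from a PDB or mmCIF file.

    Gzip-compressed variants are accepted. Multi-model files (NMR
    ensembles) contribute only their first model. Residues lacking a
    Calpha atom are skipped with a logged count; alternate locations
    resolve to the highest-occupancy conformer.

    Parameters
    ----------
    path : path-like
        Structure file in PDB or mmCIF format, optionally gzipped.
    chain : str, optional
        Chain name to extract. Defaults to the first chain in file order
        (single-chain predicted models are the canonical input).
    structure_id : str, optional
        Identifier for the returned trace; defaults to the file stem.

    Raises
    ------
    FormatError
        If the file cannot be parsed.
    ChainNotFoundError
        If ``chain`` names a chain absent from the first model.
    EmptyTraceError
        If the selected chain contains no Calpha atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise FormatError(f"no models in {path}")

    model = structure[0]
    if chain is None:
        if len(model) == 0:
            raise EmptyTraceError(f"no chains in first model of {path}")
        selected = model[0]
    else:
        selected = None
        for candidate in model:
            if candidate.name == chain:
                selected = candidate
                break
        if selected is None:
            names = [c.name for c in model]
            raise ChainNotFoundError(
                f"chain {chain!r} not in {path} (has {names})"
            )

    coords = []
    skipped = 0
    for residue in selected:
        atom = _best_calpha(residue)
        if atom is None:
            skipped += 1
            continue
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if skipped:
        logger.info(
            "%s chain %s: skipped %d residue(s) without a Calpha",
            path.name, selected.name, skipped,
        )
    if not coords:
        raise EmptyTraceError(
            f"chain {selected.name!r} of {path} has no Calpha atoms"
        )
    if structure_id is None:
        name = path.name
        for suffix in (".gz", ".pdb", ".cif", ".mmcif", ".ent"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        structure_id = name
    return CalphaTrace(id=structure_id, coords=np.array(coords))


def compute_distance_matrix(trace: CalphaTrace) -> DistanceImage:
    """All-versus-all Euclidean distances between Calpha positions.

    Returns a :class:`DistanceImage` with ``D`` populated and ``img``
    unset. ``D`` is symmetric with a zero diagonal.
    """
    if not np.all(np.isfinite(trace.coords)):
        raise InvalidInputError("trace contains non-finite coordinates")
    if trace.length == 1:
        D = np.zeros((1, 1), dtype=np.float64)
    else:
        D = squareform(pdist(trace.coords))
    return DistanceImage(id=trace.id, D=D)


def normalize_matrix(D: np.ndarray) -> np.ndarray:
    """Map a distance matrix onto the 0-255 integer scale.

    Each entry x becomes ``int(255 * (x - min) / (max - min))`` with
    ``int`` truncating toward zero, so the global minimum maps to 0 and
    the global maximum to exactly 255. A constant (zero-range) matrix —
    including the 1x1 degenerate case — maps to all zeros.
    """
    D = np.asarray(D, dtype=np.float64)
    if not np.all(np.isfinite(D)):
        raise InvalidInputError("distance matrix contains non-finite values")
    lo = D.min()
    hi = D.max()
    if hi == lo:
        return np.zeros(D.shape, dtype=np.uint8)
    # ratio first: the global maximum divides to exactly 1.0, so it maps
    # to exactly 255 regardless of rounding in the multiply
    scaled = np.trunc(255.0 * ((D - lo) / (hi - lo)))
    return scaled.astype(np.uint8)


def distance_image(trace: CalphaTrace) -> DistanceImage:
    """Convenience: distance matrix plus its normalized image in one step."""
    di = compute_distance_matrix(trace)
    di.img = normalize_matrix(di.D)
    return di


def write_matrix_tsv(di: DistanceImage, path: str | Path) -> None:
    """Debug output: the raw distance matrix as TSV (angstrom, 4 dp)."""
    np.savetxt(path, di.D, fmt="%.4f", delimiter="\t")


def write_image_png(di: DistanceImage, path: str | Path) -> None:
    """Debug output: the normalized matrix as an 8-bit grayscale PNG."""
    import imageio.v3 as iio

    if di.img is None:
        raise InvalidInputError("image not computed; call normalize_matrix")
    iio.imwrite(Path(path), di.img)
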