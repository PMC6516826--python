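"""Dendritic-arbor morphometry from SWC reconstructions.

Descriptors follow the classical stellate / disc-shaped distinction for
inferior colliculus neurons: a principal-component analysis of the dendrite
coordinates yields the arbor's length and width axes; the 3D length-to-width
extent ratio classifies the cell (ratio < 3 stellate, >= 3 disc-shaped), the
2D first principal direction gives the in-plane orientation relative to the
medial-lateral axis, and the spread perpendicular to the ~45 deg isofrequency
lamina quantifies how many laminae the arbor may cross.

Coordinate convention (coronal view of the left IC from caudal): x runs
medial -> lateral, y runs dorsal -> ventral, z is rostro-caudal depth.
Angles are reported counter-clockwise from the medial-lateral (horizontal)
axis as they appear on the standard display (dorsal up), folded into
[0, 180).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ConfigurationError, InsufficientDataError

SOMA_TAG = 1
SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]

#: Relative eigenvalue gap below which the orientation is indeterminate.
ISOTROPY_TOL = 1e-9


@dataclass
class NeuronMorphology:
    """An SWC tree plus side / subdivision annotations.

    ``nodes`` has the seven SWC columns; soma nodes carry structure tag 1.
    """

    nodes: pd.DataFrame
    side: Optional[str] = None            # left | right
    subdivision: Optional[str] = None     # ICc | ICd | IClc
    neuron_id: Optional[str] = None

    def __post_init__(self) -> None:
        missing = [c for c in SWC_COLUMNS if c not in self.nodes.columns]
        if missing:
            raise FormatError(f"nodes table missing columns {missing}")
        if not np.isfinite(self.nodes[["x", "y", "z"]].to_numpy()).all():
            raise FormatError("non-finite coordinates")

    @property
    def soma_ids(self) -> set:
        return set(self.nodes.loc[self.nodes["type"] == SOMA_TAG, "id"])

    @property
    def soma_position(self) -> np.ndarray:
        soma = self.nodes[self.nodes["type"] == SOMA_TAG]
        if soma.empty:
            raise FormatError("no soma node (structure tag 1)")
        return soma[["x", "y", "z"]].to_numpy().mean(axis=0)

    def dendrite_coords(self) -> np.ndarray:
        """(N, 3) coordinates of all non-soma nodes."""
        return self.nodes.loc[self.nodes["type"] != SOMA_TAG,
                              ["x", "y", "z"]].to_numpy(dtype=float)


@dataclass
class PrincipalAxes:
    """Ordered principal directions and per-axis coordinate extents."""

    directions: np.ndarray    # (dims, dims); column k = k-th axis
    extents: np.ndarray       # ranges after rotation into the eigenbasis
    eigenvalues: np.ndarray   # descending
    degenerate: bool = False


@dataclass
class MorphometricProfile:
    neuron_id: Optional[str] = None
    first_axis_length: Optional[float] = None
    second_axis_length: Optional[float] = None
    length_width_ratio: Optional[float] = None
    shape_class: Optional[str] = None
    orientation_deg: Optional[float] = None
    laminar_spread: Optional[float] = None
    within_15deg_of_lamina: Optional[bool] = None
    n_primary_dendrites: Optional[int] = None
    spiny: Optional[bool] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# SWC I/O

def read_swc(path: Union[str, Path, io.TextIOBase],
             side: Optional[str] = None,
             subdivision: Optional[str] = None,
             neuron_id: Optional[str] = None) -> NeuronMorphology:
    """Parse an SWC file into a :class:`NeuronMorphology`.

    Errors (non-numeric fields, orphan parent references, cyclic parent
    chains) are reported with the offending line number.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
        if neuron_id is None:
            neuron_id = Path(path).stem
    else:
        text = path.read()
    rows, linenos = [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(f"line {lineno}: expected 7 fields, got {len(parts)}")
        try:
            row = (int(parts[0]), int(parts[1]), float(parts[2]),
                   float(parts[3]), float(parts[4]), float(parts[5]),
                   int(parts[6]))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        rows.append(row)
        linenos.append(lineno)
    if not rows:
        raise FormatError("empty SWC file")
    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    if nodes["id"].duplicated().any():
        dup = nodes.loc[nodes["id"].duplicated(), "id"].iloc[0]
        raise FormatError(f"duplicate node id {dup}")
    ids = set(nodes["id"])
    parent_of = dict(zip(nodes["id"], nodes["parent"]))
    for lineno, (nid, parent) in zip(linenos, parent_of.items()):
        if parent != -1 and parent not in ids:
            raise FormatError(f"line {lineno}: parent id {parent} not defined")
    # cycle check by walking each node to a root
    for lineno, nid in zip(linenos, nodes["id"]):
        seen = set()
        cur = nid
        while cur != -1:
            if cur in seen:
                raise FormatError(f"line {lineno}: cyclic parent chain at node {nid}")
            seen.add(cur)
            cur = parent_of[cur]
    return NeuronMorphology(nodes=nodes, side=side, subdivision=subdivision,
                            neuron_id=neuron_id)


def write_swc(m: NeuronMorphology, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for row in m.nodes.itertuples(index=False):
            fh.write(f"{row.id} {row.type} {row.x:.6f} {row.y:.6f} "
                     f"{row.z:.6f} {row.radius:.6f} {row.parent}\n")


# ---------------------------------------------------------------------------
# Operations

def mirror_to_left(m: NeuronMorphology) -> NeuronMorphology:
    """Reflect right-side neurons about the soma's sagittal (x) axis.

    Left-side neurons are returned unchanged (same coordinates); applying
    the operation twice is the identity.
    """
    if m.side not in ("left", "right"):
        raise ConfigurationError(f"unknown side {m.side!r}")
    if m.side == "left":
        return NeuronMorphology(m.nodes.copy(), side="left",
                                subdivision=m.subdivision, neuron_id=m.neuron_id)
    x0 = m.soma_position[0]
    nodes = m.nodes.copy()
    nodes["x"] = 2.0 * x0 - nodes["x"]
    return NeuronMorphology(nodes, side="left", subdivision=m.subdivision,
                            neuron_id=m.neuron_id)


def principal_axes(m_or_coords, dims: int = 2) -> PrincipalAxes:
    """PCA of the dendrite coordinates (soma excluded, nodes unweighted).

    Returns eigenvectors of the coordinate covariance ordered by decreasing
    eigenvalue, and per-axis extents: the min-to-max coordinate ranges after
    rotating the coordinate set into the eigenbasis.  The first axis's sign
    is fixed so its medial-lateral component is non-negative.  Degenerate
    inputs (too few / collinear points) set the ``degenerate`` flag instead
    of raising.
    """
    if dims not in (2, 3):
        raise ConfigurationError("dims must be 2 or 3")
    coords = (m_or_coords.dendrite_coords()
              if isinstance(m_or_coords, NeuronMorphology)
              else np.asarray(m_or_coords, dtype=float))
    coords = coords[:, :dims]
    n = coords.shape[0]
    if n < dims + 1:
        return PrincipalAxes(np.eye(dims), np.zeros(dims), np.zeros(dims),
                             degenerate=True)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for k in range(dims):  # deterministic signs: leading nonzero component >= 0
        col = evecs[:, k]
        lead = col[np.argmax(np.abs(col) > 1e-12)] if np.any(np.abs(col) > 1e-12) else 1.0
        if col[0] < 0 or (col[0] == 0 and lead < 0):
            evecs[:, k] = -col
    rotated = centered @ evecs
    extents = rotated.max(axis=0) - rotated.min(axis=0)
    degenerate = bool(evals[0] <= 0 or
                      (dims == 2 and extents[1] == 0 and extents[0] == 0))
    return PrincipalAxes(evecs, extents, evals, degenerate=degenerate)


def classify_shape(axes: PrincipalAxes) -> tuple[str, float]:
    """Stellate / disc-shaped from the 3D length-to-width extent ratio.

    Ratio < 3 is stellate; >= 3 is disc-shaped.  A second extent of zero
    (perfect line) is disc-shaped with an infinite ratio.
    """
    first, second = float(axes.extents[0]), float(axes.extents[1])
    if first <= 0:
        raise InsufficientDataError("degenerate extents: first axis length is 0")
    if second == 0:
        return "disc_shaped", float("inf")
    ratio = first / second
    return ("stellate" if ratio < 3.0 else "disc_shaped"), ratio


def orientation_angle(axes: PrincipalAxes,
                      lamina_angle_deg: float = 45.0,
                      within_deg: float = 15.0,
                      ) -> tuple[Optional[float], Optional[bool]]:
    """Orientation of the first 2D principal direction, in degrees CCW from
    the medial-lateral axis (display convention: dorsal up), in [0, 180).

    Also reports whether the angle lies within ``within_deg`` of the
    ``lamina_angle_deg`` laminar plane.  Near-isotropic arbors (eigenvalue
    gap below ``ISOTROPY_TOL``) have indeterminate orientation -> (None, None).
    """
    if axes.degenerate:
        return None, None
    lam = axes.eigenvalues
    if lam[0] <= 0 or (lam[0] - lam[1]) / lam[0] < ISOTROPY_TOL:
        return None, None
    vx, vy = axes.directions[0, 0], axes.directions[1, 0]
    # y increases ventrally (downward); display angle uses dorsal-up axis
    ang = np.degrees(np.arctan2(-vy, vx)) % 180.0
    d = abs(ang - lamina_angle_deg)
    within = min(d, 180.0 - d) <= within_deg
    return float(ang), bool(within)


def laminar_spread(m_or_coords, lamina_angle_deg: float = 45.0) -> float:
    """Extent of the dendritic arbor perpendicular to the laminar plane (um).

    The lamina is a line at ``lamina_angle_deg`` (display CCW from the
    medial-lateral axis) in the coronal plane; the spread is the range of the
    dendrite coordinates projected on the in-plane unit normal.
    """
    coords = (m_or_coords.dendrite_coords()
              if isinstance(m_or_coords, NeuronMorphology)
              else np.asarray(m_or_coords, dtype=float))
    if coords.shape[0] < 2:
        raise InsufficientDataError("need >= 2 dendrite points")
    th = np.radians(lamina_angle_deg)
    # display normal (-sin, cos) with display-y = -y  =>  raw (-sin, -cos)
    normal = np.array([-np.sin(th), -np.cos(th)])
    proj = coords[:, :2] @ normal
    return float(proj.max() - proj.min())


def count_primary_dendrites(m: NeuronMorphology) -> int:
    """Number of dendritic stems whose parent is a soma node."""
    soma = m.soma_ids
    if not soma:
        raise FormatError("no soma node (structure tag 1)")
    dend = m.nodes[m.nodes["type"] != SOMA_TAG]
    return int(dend["parent"].isin(soma).sum())


def morphometric_profile(m: NeuronMorphology,
                         lamina_angle_deg: float = 45.0,
                         spiny: Optional[bool] = None) -> MorphometricProfile:
    """All arbor descriptors for one neuron (right-side cells are mirrored
    to the left before measurement)."""
    if m.side == "right":
        m = mirror_to_left(m)
    ax3 = principal_axes(m, dims=3)
    ax2 = principal_axes(m, dims=2)
    shape, ratio = classify_shape(ax3)
    ang, within = orientation_angle(ax2, lamina_angle_deg=lamina_angle_deg)
    return MorphometricProfile(
        neuron_id=m.neuron_id,
        first_axis_length=float(ax3.extents[0]),
        second_axis_length=float(ax3.extents[1]),
        length_width_ratio=ratio,
        shape_class=shape,
        orientation_deg=ang,
        laminar_spread=laminar_spread(m, lamina_angle_deg),
        within_15deg_of_lamina=within,
        n_primary_dendrites=count_primary_dendrites(m),
        spiny=spiny,
    )
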