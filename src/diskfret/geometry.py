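"""Idealized geometry of two coupled ring-array chromophore disks.

Each disk assembly is modeled as one or two stacked rings of
uniformly spaced chromophore attachment sites.  Two disks are coupled
side-by-side with parallel, coaxial-normal orientation, and the
in-plane center separation is solved so that the closest inter-disk
site-site distance equals a calibration target (7.5 nm by default,
the estimated closest donor-acceptor pair in the real assembly).

From the resulting coordinates the module computes the inter-disk
distance distribution and the distance-only Forster pathway weights

    p_i = R_i^-6 / sum_j R_j^-6,

i.e. the fraction of total donor->acceptor energy transfer attributed
to each site pair if only the 1/R^6 distance dependence mattered
(no dipole-orientation factors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "RingArraySpec",
    "ChromophoreSet",
    "CoupledDiskGeometry",
    "PathwayTable",
    "ring_radius",
    "build_disk",
    "couple_disks",
    "pathway_table",
    "rate_fold_change",
    "modified_monomer_count",
]


class GeometryError(ValueError):
    """Invalid geometry specification or unsolvable calibration."""


@dataclass(frozen=True)
class RingArraySpec:
    """Parameters of one disk assembly's chromophore ring array.

    Parameters
    ----------
    sites_per_ring : int
        Chromophore sites per ring (17 for a cpTMV disk layer).
    nn_spacing : float
        Distance in nm between adjacent sites in the same ring
        (~1.95 nm for neighboring chromophores on one disk).
    n_layers : int
        1 or 2 rings per assembly (2 for a double-layer disk).
    layer_separation : float
        Axial distance in nm between the two rings of a double disk.
    azimuthal_offset : float
        Rotation in radians of the second layer relative to the first.
    """

    sites_per_ring: int = 17
    nn_spacing: float = 1.95
    n_layers: int = 2
    layer_separation: float = 2.5
    azimuthal_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.sites_per_ring < 2:
            raise GeometryError("sites_per_ring must be >= 2")
        if not self.nn_spacing > 0:
            raise GeometryError("nn_spacing must be positive")
        if self.n_layers not in (1, 2):
            raise GeometryError("n_layers must be 1 or 2")
        if self.layer_separation < 0:
            raise GeometryError("layer_separation must be >= 0")

    @property
    def n_sites(self) -> int:
        return self.sites_per_ring * self.n_layers

    @property
    def radius(self) -> float:
        return ring_radius(self.sites_per_ring, self.nn_spacing)


@dataclass(frozen=True)
class ChromophoreSet:
    """Chromophore site coordinates of one disk.

    ``coordinates`` is an (n_sites, 3) array in nm; ``layer_index`` and
    ``site_index`` identify each row's ring and azimuthal position.
    """

    coordinates: np.ndarray
    disk_label: str
    layer_index: np.ndarray
    site_index: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError("coordinates must be an (n, 3) array")
        object.__setattr__(self, "coordinates", coords)

    def __len__(self) -> int:
        return len(self.coordinates)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates, columns=["x_nm", "y_nm", "z_nm"])
        df.insert(0, "site_index", self.site_index)
        df.insert(0, "layer_index", self.layer_index)
        df.insert(0, "disk_label", self.disk_label)
        return df


@dataclass(frozen=True)
class CoupledDiskGeometry:
    """Two disks with parallel coaxial normals, coupled side-by-side."""

    donor_set: ChromophoreSet
    acceptor_set: ChromophoreSet
    center_separation: float
    closest_pair: float

    def distances(self) -> np.ndarray:
        """All inter-disk site-site distances, shape (n_donor, n_acceptor)."""
        d = self.donor_set.coordinates[:, None, :] - self.acceptor_set.coordinates[None, :, :]
        return np.linalg.norm(d, axis=-1)

    @property
    def min_distance(self) -> float:
        return float(self.distances().min())

    @property
    def max_distance(self) -> float:
        return float(self.distances().max())

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.donor_set.to_frame(), self.acceptor_set.to_frame()],
            ignore_index=True,
        )

    def export(self, path) -> None:
        """Write site coordinates as tab-delimited text."""
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PathwayTable:
    """Donor-acceptor pairs with distances and normalized 1/R^6 weights.

    Rows are sorted by ascending distance; weights sum to 1.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("donor_idx", "acceptor_idx", "R_nm", "weight")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise GeometryError(f"pathway table missing columns {sorted(missing)}")
        if len(self.table) == 0:
            raise GeometryError("pathway table is empty")
        if (self.table["R_nm"] <= 0).any():
            raise GeometryError("all pathway distances must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def distances(self) -> np.ndarray:
        return self.table["R_nm"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()

    @property
    def max_weight(self) -> float:
        return float(self.weights.max())

    def is_normalized(self, tol: float = 1e-9) -> bool:
        return abs(float(self.weights.sum()) - 1.0) <= tol

    def export(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def ring_radius(n: int, s: float) -> float:
    """Radius of a ring of ``n`` uniformly spaced points with adjacent
    spacing ``s`` (chord inversion): r = s / (2 sin(pi/n)).
    """
    if n < 2:
        raise GeometryError("need at least 2 sites per ring")
    if not s > 0:
        raise GeometryError("spacing must be positive")
    return s / (2.0 * math.sin(math.pi / n))


def build_disk(
    spec: RingArraySpec,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    label: str = "donor",
    reference_azimuth: float = 0.0,
) -> ChromophoreSet:
    """Place the chromophore sites of one disk.

    The disk normal is the z axis.  Each ring lies in a plane
    perpendicular to z; for a double disk the rings sit at
    z = center_z +/- layer_separation/2.  One site of the first ring is
    aligned to ``reference_azimuth`` (measured in the xy plane from +x),
    so that a site can be pointed exactly at a partner disk.
    """
    r = spec.radius
    cx, cy, cz = center
    coords, layers, sites = [], [], []
    if spec.n_layers == 1:
        z_offsets = [0.0]
    else:
        z_offsets = [+spec.layer_separation / 2.0, -spec.layer_separation / 2.0]
    for layer, dz in enumerate(z_offsets):
        theta = (
            reference_azimuth
            + layer * spec.azimuthal_offset
            + 2.0 * np.pi * np.arange(spec.sites_per_ring) / spec.sites_per_ring
        )
        coords.append(
            np.column_stack(
                [
                    cx + r * np.cos(theta),
                    cy + r * np.sin(theta),
                    np.full(spec.sites_per_ring, cz + dz),
                ]
            )
        )
        layers.append(np.full(spec.sites_per_ring, layer, dtype=int))
        sites.append(np.arange(spec.sites_per_ring, dtype=int))
    return ChromophoreSet(
        coordinates=np.vstack(coords),
        disk_label=label,
        layer_index=np.concatenate(layers),
        site_index=np.concatenate(sites),
    )


def couple_disks(
    spec_d: RingArraySpec,
    spec_a: RingArraySpec,
    closest_pair: float = 7.5,
) -> CoupledDiskGeometry:
    """Couple two disks side-by-side so the minimum inter-disk
    site-site distance equals ``closest_pair``.

    Both disks share the z axis direction as normal; centers lie on the
    x axis.  One donor site faces +x and one acceptor site faces -x, so
    for same-height layers the closest pair lies on the inter-center
    axis and the exact solution is

        center_separation = closest_pair + r_d + r_a.
    """
    if not closest_pair > 0:
        raise GeometryError("closest_pair must be positive")
    sep = closest_pair + spec_d.radius + spec_a.radius
    if sep <= 0:
        raise GeometryError("unsolvable center separation")
    donor = build_disk(spec_d, (0.0, 0.0, 0.0), "donor", reference_azimuth=0.0)
    acceptor = build_disk(spec_a, (sep, 0.0, 0.0), "acceptor", reference_azimuth=np.pi)
    geom = CoupledDiskGeometry(
        donor_set=donor,
        acceptor_set=acceptor,
        center_separation=sep,
        closest_pair=closest_pair,
    )
    if abs(geom.min_distance - closest_pair) > 1e-6:
        raise GeometryError(
            f"calibration failed: realized minimum {geom.min_distance:.9f} nm "
            f"!= target {closest_pair} nm"
        )
    return geom


def pathway_table(geom: CoupledDiskGeometry, top_k: int | None = None) -> PathwayTable:
    """Distance-only pathway contributions over donor-acceptor pairs.

    Weights are p_i = R_i^-6 / sum_j R_j^-6 over all inter-disk pairs,
    or renormalized over the ``top_k`` nearest pairs if requested.
    """
    dist = geom.distances()
    nd, na = dist.shape
    if nd == 0 or na == 0:
        raise GeometryError("empty geometry")
    di, ai = np.meshgrid(np.arange(nd), np.arange(na), indexing="ij")
    df = pd.DataFrame(
        {
            "donor_idx": di.ravel(),
            "acceptor_idx": ai.ravel(),
            "R_nm": dist.ravel(),
        }
    ).sort_values("R_nm", kind="stable", ignore_index=True)
    if top_k is not None:
        if not 1 <= top_k <= len(df):
            raise GeometryError(f"top_k must be in [1, {len(df)}]")
        df = df.iloc[:top_k].reset_index(drop=True)
    w = df["R_nm"].to_numpy() ** -6.0
    df["weight"] = w / w.sum()
    return PathwayTable(df)


def rate_fold_change(R_from: float, R_to: float) -> float:
    """Factor by which the pairwise transfer timescale shortens when the
    donor-acceptor distance changes from ``R_from`` to ``R_to``:
    (R_from / R_to)^6.
    """
    if not (R_from > 0 and R_to > 0):
        raise GeometryError("distances must be positive")
    return (R_from / R_to) ** 6


def modified_monomer_count(
    fraction: float, monomers_per_assembly: int
) -> tuple[float, int]:
    """Expected number of modified monomers per assembly.

    Returns ``(fraction * monomers, nearest integer)``, e.g. a 31%
    modification yield over a 34-monomer assembly gives 10.54 (~10.5
    modifications on average).
    """
    if not 0 <= fraction <= 1:
        raise GeometryError("fraction must lie in [0, 1]")
    if monomers_per_assembly <= 0:
        raise GeometryError("monomers_per_assembly must be positive")
    exact = fraction * monomers_per_assembly
    return exact, round(exact)
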