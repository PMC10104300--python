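"""Synthetic alignments, grouped families and toy helical structures.

Every generator is a pure function of its spec and seed, and returns the
ground truth alongside the data (true column distributions, divergent-site
keys, injected displacement magnitudes) so that estimator recovery can be
tested end to end without any database downloads.

Alignment columns are modelled as independent: a per-site amino-acid
distribution is drawn once (explicitly given, or sampled from a symmetric
Dirichlet whose concentration controls conservation), then rows are drawn
i.i.d. from it and gaps injected independently.  This matches the object
the conservation estimators target — the column distribution — but carries
no phylogenetic correlation between rows, unlike real families.

Toy structures are ideal poly-alanine α-helices (rise 1.5 Å and 100° turn
per residue) with backbone N, CA, C, O atoms, placed on arbitrary axes;
per-residue displacement and rigid-motion perturbations provide fixtures
with known deviation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import gemmi
import numpy as np

from famcons.conservation import LOG20
from famcons.sequence_io import AMINO_ACIDS, GAP, ProjectedAlignment
from famcons.structure import StructureModel

# ideal alpha-helix geometry
HELIX_RISE = 1.5          # Å per residue along the axis
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS_CA = 2.3     # Å, CA distance from the axis


@dataclass(frozen=True)
class SiteSpec:
    """One column's generator: an explicit 20-vector or a Dirichlet draw.

    ``concentration`` is the symmetric Dirichlet parameter: small values
    (≈0.01) give near-degenerate, conserved columns; large values (≈100)
    approach the uniform distribution over all 20 types.
    """

    probs: tuple[float, ...] | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if (self.probs is None) == (self.concentration is None):
            raise ValueError("specify exactly one of probs or concentration")
        if self.probs is not None:
            p = np.asarray(self.probs, dtype=float)
            if p.shape != (20,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("probs must be a length-20 vector summing to 1")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("concentration must be > 0")

    @classmethod
    def fixed(cls, residue: str) -> "SiteSpec":
        """A fully conserved column of one residue type."""
        p = np.zeros(20)
        p[AMINO_ACIDS.index(residue)] = 1.0
        return cls(probs=tuple(p))

    @classmethod
    def uniform(cls) -> "SiteSpec":
        return cls(probs=tuple(np.full(20, 1 / 20)))


@dataclass(frozen=True)
class FamilySpec:
    """A synthetic protein family: rows i.i.d. per site, gaps injected."""

    n_sequences: int
    sites: tuple[SiteSpec, ...]
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not self.sites:
            raise ValueError("at least one site is required")
        if not (0 <= self.gap_rate < 1):
            raise ValueError("gap_rate must be in [0, 1)")


def _realize_distributions(spec: FamilySpec, rng: np.random.Generator) -> np.ndarray:
    dists = np.empty((len(spec.sites), 20))
    for i, site in enumerate(spec.sites):
        if site.probs is not None:
            dists[i] = site.probs
        else:
            dists[i] = rng.dirichlet(np.full(20, site.concentration))
    return dists


def _draw_rows(
    dists: np.ndarray, n: int, gap_rate: float, rng: np.random.Generator
) -> np.ndarray:
    aa = np.array(list(AMINO_ACIDS))
    n_sites = dists.shape[0]
    cols = np.empty((n, n_sites), dtype="<U1")
    for i in range(n_sites):
        cols[:, i] = aa[rng.choice(20, size=n, p=dists[i])]
    if gap_rate > 0:
        mask = rng.random((n, n_sites)) < gap_rate
        cols[mask] = GAP
    return cols


def true_entropy(dist: np.ndarray) -> float:
    """Base-20 entropy of a known column distribution (ground truth)."""
    p = np.asarray(dist, dtype=float)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() / LOG20)


def generate_family(spec: FamilySpec) -> tuple[ProjectedAlignment, np.ndarray]:
    """Draw a synthetic family; returns the alignment and the realized
    true per-site distributions (shape n_sites x 20)."""
    rng = np.random.default_rng(spec.seed)
    dists = _realize_distributions(spec, rng)
    cols = _draw_rows(dists, spec.n_sequences, spec.gap_rate, rng)
    ids = [f"seq{i + 1:05d}" for i in range(spec.n_sequences)]
    aln = ProjectedAlignment(
        reference_id="synthetic_ref",
        ids=ids,
        site_numbers=list(range(1, len(spec.sites) + 1)),
        columns=cols,
    )
    return aln, dists


def generate_two_groups(
    shared_spec: FamilySpec,
    divergent_sites: Mapping[int, tuple[Sequence[float], Sequence[float]]],
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> tuple[ProjectedAlignment, dict[int, tuple[np.ndarray, np.ndarray]]]:
    """Two groups sharing column distributions except at chosen sites.

    ``divergent_sites`` maps 1-based site numbers to a pair of explicit
    distributions (group 1, group 2).  Each group has
    ``shared_spec.n_sequences`` rows.  Returns the combined alignment with
    ``row_groups`` labels and the divergent-site key for recovery testing.
    """
    n_sites = len(shared_spec.sites)
    for site in divergent_sites:
        if not (1 <= site <= n_sites):
            raise ValueError(f"divergent site {site} outside 1..{n_sites}")
    rng = np.random.default_rng(shared_spec.seed)
    dists = _realize_distributions(shared_spec, rng)
    dists1, dists2 = dists.copy(), dists.copy()
    key: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for site, (p1, p2) in divergent_sites.items():
        p1 = np.asarray(p1, dtype=float)
        p2 = np.asarray(p2, dtype=float)
        for name, p in (("dist_1", p1), ("dist_2", p2)):
            if p.shape != (20,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{name} at site {site} is not a valid distribution")
        dists1[site - 1] = p1
        dists2[site - 1] = p2
        key[site] = (p1, p2)

    n = shared_spec.n_sequences
    rows1 = _draw_rows(dists1, n, shared_spec.gap_rate, rng)
    rows2 = _draw_rows(dists2, n, shared_spec.gap_rate, rng)
    ids = [f"g1_{i + 1:05d}" for i in range(n)] + [f"g2_{i + 1:05d}" for i in range(n)]
    aln = ProjectedAlignment(
        reference_id="synthetic_ref",
        ids=ids,
        site_numbers=list(range(1, n_sites + 1)),
        columns=np.vstack([rows1, rows2]),
        row_groups=[group_labels[0]] * n + [group_labels[1]] * n,
    )
    return aln, key


@dataclass(frozen=True)
class HelixPlacement:
    """One ideal helix: residue count, axis origin and axis direction."""

    length: int
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError("helix length must be >= 4")
        if np.linalg.norm(self.direction) == 0:
            raise ValueError("axis direction must be non-zero")


@dataclass(frozen=True)
class ToyStructureSpec:
    """A toy structure: one chain of consecutive ideal helices."""

    helices: tuple[HelixPlacement, ...]
    chain: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.helices:
            raise ValueError("at least one helix is required")


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Proper rotation taking the z-axis onto ``direction`` (normalized)."""
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)

# backbone atom placement relative to the CA helical track, as fractional
# residue offsets along the helix and radii from the axis (idealized)
_BACKBONE_TRACK = {
    "N": (-0.38, 1.6),
    "CA": (0.0, HELIX_RADIUS_CA),
    "C": (0.42, 1.7),
    "O": (0.48, 2.1),
}


def generate_toy_structure(spec: ToyStructureSpec) -> StructureModel:
    """Build a deterministic poly-alanine structure of ideal helices.

    Consecutive Cα-Cα distances are ≈3.8 Å as in real α-helices; residues
    are numbered consecutively along the chain across helices.
    """
    structure = gemmi.Structure()
    structure.name = "toy"
    model = gemmi.Model("1")
    chain = gemmi.Chain(spec.chain)
    resnum = 0
    serial = 0
    for helix in spec.helices:
        R = _rotation_to(np.asarray(helix.direction, dtype=float))
        origin = np.asarray(helix.origin, dtype=float)
        for i in range(helix.length):
            resnum += 1
            residue = gemmi.Residue()
            residue.name = "ALA"
            residue.seqid = gemmi.SeqId(resnum, " ")
            residue.het_flag = "A"
            for atom_name, (offset, radius) in _BACKBONE_TRACK.items():
                t = i + offset
                theta = np.radians(HELIX_TWIST * t)
                local = np.array(
                    [radius * np.cos(theta), radius * np.sin(theta), HELIX_RISE * t]
                )
                pos = R @ local + origin
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element("N" if atom_name == "N" else
                                             "O" if atom_name == "O" else "C")
                atom.pos = gemmi.Position(*pos)
                atom.occ = 1.0
                atom.b_iso = 0.0
                serial += 1
                atom.serial = serial
                residue.add_atom(atom)
            chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    return StructureModel(structure)


def add_pseudo_atom(
    model: StructureModel,
    chain: str,
    resnum: int,
    atom_name: str,
    position: Sequence[float],
    element: str = "O",
) -> None:
    """Place an explicit side-chain pseudo-atom (donor/acceptor) for
    contact-detection fixtures; modifies the model in place."""
    residue = model.get_residue(chain, resnum)
    if residue is None:
        raise KeyError(f"residue {chain}{resnum} not in model")
    atom = gemmi.Atom()
    atom.name = atom_name
    atom.element = gemmi.Element(element)
    atom.pos = gemmi.Position(*position)
    atom.occ = 1.0
    atom.b_iso = 0.0
    residue.add_atom(atom)


def perturb_structure(
    model: StructureModel,
    displacements: Mapping[tuple[str, int], Sequence[float]] | None = None,
    rigid: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[StructureModel, dict[tuple[str, int], float]]:
    """Translate listed residues by given vectors, then optionally apply a
    global rigid motion.  Returns the new model and the ground-truth
    displacement magnitude per listed residue."""
    out = model.copy()
    magnitudes: dict[tuple[str, int], float] = {}
    if displacements:
        for (chain, num), vec in displacements.items():
            residue = out.get_residue(chain, num)
            if residue is None:
                raise KeyError(f"residue {chain}{num} not in model")
            v = np.asarray(vec, dtype=float)
            for atom in residue:
                p = np.array([atom.pos.x, atom.pos.y, atom.pos.z]) + v
                atom.pos = gemmi.Position(*p)
            magnitudes[(chain, num)] = float(np.linalg.norm(v))
    if rigid is not None:
        rotation, translation = rigid
        out.transform(np.asarray(rotation, dtype=float), np.asarray(translation, dtype=float))
    return out, magnitudes


def random_rotation(seed: int) -> np.ndarray:
    """A uniformly random proper rotation matrix (for rigid perturbations)."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
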