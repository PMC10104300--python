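"""Crystal-structure analyses: superposition, deviation profiles, contact
networks, conservation painting and mutation overlap.

The analyses target GST-fold proteins whose core is a bundle of helices
(in GDAP1: α3, α6, α7 and α8, stapled together by the α6-α7 loop that
folds back into the core).  Provided operations:

* rigid least-squares superposition of a variant structure onto wild type
  and the per-residue Cα deviation profile after the fit;
* extraction of polar (hydrogen-bond) and ionic (salt-bridge) contacts
  between configured helices using heavy-atom distance/angle criteria —
  crystal structures carry no hydrogens, so donors are identified from
  residue chemistry and the donor-antecedent angle serves as a proxy for
  hydrogen geometry;
* mapping per-site conservation scores into the B-factor column for
  visualisation;
* classifying residues by membership in the disease-mutation list and the
  conserved-site list, including the residues contacting a focus segment
  such as the α6-α7 loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int]  # (chain name, author residue number)

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Hydrogen-bond donor atoms per residue type, mapped to the covalently
# bonded heavy-atom antecedent used for the angle proxy.  Backbone N is a
# donor in every amino acid (antecedent CA as within-residue proxy).
_SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "LYS": {"NZ": "CE"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "TRP": {"NE1": "CD1"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
}

# Hydrogen-bond acceptors; backbone carbonyl O (and terminal OXT) accept in
# every residue type.
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

# Charged side-chain groups for ionic (salt-bridge) contacts.
_POSITIVE_ATOMS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_NEGATIVE_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


class StructureError(ValueError):
    """Raised for unreadable or degenerate structure input."""


class StructureModel:
    """A single-model protein structure with author residue numbering.

    Thin wrapper around a :class:`gemmi.Structure` holding only the first
    model, with alternate locations already resolved to the highest
    occupancy conformer.  Waters and other heteroatoms are retained but
    flagged; amino-acid residues lacking a Cα are kept and flagged.
    """

    def __init__(self, structure: gemmi.Structure):
        self.structure = structure
        self.missing_ca: list[ResidueKey] = []
        self.hetero: list[ResidueKey] = []
        self._index_flags()

    def _index_flags(self) -> None:
        self.missing_ca = []
        self.hetero = []
        for chain_name, residue in self.residues():
            if residue.name in STANDARD_AA:
                if residue.find_atom("CA", "*") is None:
                    self.missing_ca.append((chain_name, residue.seqid.num))
            else:
                self.hetero.append((chain_name, residue.seqid.num))

    @property
    def model(self) -> gemmi.Model:
        return self.structure[0]

    def residues(self) -> Iterable[tuple[str, gemmi.Residue]]:
        for chain in self.model:
            for residue in chain:
                yield chain.name, residue

    def chain_names(self) -> list[str]:
        return [chain.name for chain in self.model]

    def get_residue(self, chain: str, seqid: int) -> gemmi.Residue | None:
        for ch in self.model:
            if ch.name != chain:
                continue
            for residue in ch:
                if residue.seqid.num == seqid:
                    return residue
        return None

    def ca_positions(
        self, selection: Iterable[ResidueKey] | None = None
    ) -> dict[ResidueKey, np.ndarray]:
        """Cα coordinates keyed by (chain, residue number)."""
        wanted = set(selection) if selection is not None else None
        out: dict[ResidueKey, np.ndarray] = {}
        for chain_name, residue in self.residues():
            key = (chain_name, residue.seqid.num)
            if wanted is not None and key not in wanted:
                continue
            ca = residue.find_atom("CA", "*")
            if ca is not None:
                out[key] = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
        return out

    def copy(self) -> "StructureModel":
        return StructureModel(self.structure.clone())

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply x -> R x + t to every atom in place."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for _, residue in self.residues():
            for atom in residue:
                p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                q = R @ p + t
                atom.pos = gemmi.Position(*q)

    def write_pdb(self, path: str | Path) -> None:
        self.structure.setup_entities()
        self.structure.write_pdb(str(path))


def _resolve_altlocs(structure: gemmi.Structure) -> None:
    """Keep, per residue and atom name, the conformer with the highest
    occupancy; occupancy ties resolve to the alphabetically first altloc."""
    for model in structure:
        for chain in model:
            for residue in chain:
                by_name: dict[str, list[int]] = {}
                for i, atom in enumerate(residue):
                    by_name.setdefault(atom.name, []).append(i)
                to_drop: list[int] = []
                for _, idxs in by_name.items():
                    if len(idxs) < 2:
                        continue
                    best = min(
                        idxs,
                        key=lambda i: (-residue[i].occ, residue[i].altloc or "A"),
                    )
                    to_drop.extend(i for i in idxs if i != best)
                for i in sorted(to_drop, reverse=True):
                    del residue[i]
                for atom in residue:
                    atom.altloc = "\0"


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB file; first model only, altlocs resolved by occupancy."""
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except Exception as exc:
        raise StructureError(f"cannot read structure {path}: {exc}") from exc
    if len(structure) == 0 or all(len(ch) == 0 for ch in structure[0]):
        raise StructureError(f"{path} contains no coordinates")
    while len(structure) > 1:
        del structure[len(structure) - 1]
    _resolve_altlocs(structure)
    model = StructureModel(structure)
    if model.missing_ca:
        logger.warning("%s: %d residues lack a CA atom", path.name, len(model.missing_ca))
    return model


@dataclass
class Superposition:
    """Rigid transform (x -> R x + t) mapping mobile onto target, plus RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def superpose(
    mobile: StructureModel,
    target: StructureModel,
    selection: Iterable[ResidueKey] | None = None,
) -> Superposition:
    """Least-squares optimal rigid superposition on shared Cα atoms.

    ``selection`` restricts the fit set; by default every residue with a
    Cα in both models is used.  The returned RMSD is the post-fit value
    over the fit set; the rotation is always proper (det +1).
    """
    mob = mobile.ca_positions(selection)
    tgt = target.ca_positions(selection)
    shared = sorted(set(mob) & set(tgt))
    if len(shared) < 3:
        raise StructureError(f"superposition needs >= 3 shared CA atoms, got {len(shared)}")
    mob_pos = [gemmi.Position(*mob[k]) for k in shared]
    tgt_pos = [gemmi.Position(*tgt[k]) for k in shared]
    result = gemmi.superpose_positions(tgt_pos, mob_pos)
    R = np.array(result.transform.mat.tolist())
    t = np.array(result.transform.vec.tolist())
    assert np.linalg.det(R) > 0
    return Superposition(rotation=R, translation=t, rmsd=float(result.rmsd), n_atoms=len(shared))


@dataclass
class DeviationProfile:
    """Per-residue Cα-Cα distance after superposition, plus fit RMSD."""

    table: pd.DataFrame  # columns: chain, residue, deviation
    fit_rmsd: float
    n_fit: int

    def deviation_at(self, chain: str, residue: int) -> float:
        row = self.table[(self.table["chain"] == chain) & (self.table["residue"] == residue)]
        if row.empty:
            raise KeyError((chain, residue))
        return float(row["deviation"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def ca_deviation_profile(
    variant: StructureModel,
    wildtype: StructureModel,
    fit_selection: Iterable[ResidueKey] | None = None,
    report_selection: Iterable[ResidueKey] | None = None,
) -> DeviationProfile:
    """Superpose variant onto wild type, then profile per-residue Cα deviation.

    The fit defaults to all shared Cα; ``report_selection`` restricts which
    residues are profiled (e.g. only those participating in the core
    hydrogen-bonding network) without affecting the fit.
    """
    sup = superpose(variant, wildtype, fit_selection)
    var_ca = variant.ca_positions(report_selection)
    wt_ca = wildtype.ca_positions(report_selection)
    shared = sorted(set(var_ca) & set(wt_ca))
    if not shared:
        raise StructureError("no shared CA atoms in report selection")
    rows = []
    for chain, num in shared:
        moved = sup.apply(var_ca[(chain, num)][None, :])[0]
        dev = float(np.linalg.norm(moved - wt_ca[(chain, num)]))
        rows.append({"chain": chain, "residue": num, "deviation": dev})
    table = pd.DataFrame(rows).sort_values(["chain", "residue"]).reset_index(drop=True)
    return DeviationProfile(table=table, fit_rmsd=sup.rmsd, n_fit=sup.n_atoms)


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric criteria for polar/ionic contact detection.

    hbond_max: heavy-atom donor-acceptor distance ceiling (Å).
    angle_min: minimum antecedent-donor-acceptor angle (degrees), a proxy
        for hydrogen geometry in hydrogen-free crystal structures.
    ionic_max: ceiling for charged-group N...O distances (Å).
    dedupe: "residue_pair" keeps only the closest atom pair per residue
        pair; "all_pairs" keeps every qualifying atom pair.
    """

    hbond_max: float = 3.5
    angle_min: float = 90.0
    ionic_max: float = 4.0
    dedupe: str = "residue_pair"


@dataclass
class ContactNetwork:
    """Polar/ionic residue-pair interactions with geometry annotations."""

    edges: pd.DataFrame
    criteria: ContactCriteria

    EDGE_COLUMNS = [
        "chain_a", "res_a", "resname_a", "atom_a",
        "chain_b", "res_b", "resname_b", "atom_b",
        "distance", "type", "helix_pair",
    ]

    @property
    def atom_count(self) -> int:
        return len(self.edges)

    @property
    def residue_pair_count(self) -> int:
        if self.edges.empty:
            return 0
        pairs = {
            frozenset([(r.chain_a, r.res_a), (r.chain_b, r.res_b)])
            for r in self.edges.itertuples()
        }
        return len(pairs)

    def residues(self) -> set[ResidueKey]:
        out: set[ResidueKey] = set()
        for r in self.edges.itertuples():
            out.add((r.chain_a, r.res_a))
            out.add((r.chain_b, r.res_b))
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.3f")


def _polar_atoms(residue: gemmi.Residue) -> list[dict]:
    """Donor/acceptor/charge annotation for every polar heavy atom."""
    name = residue.name
    donors = dict(_SIDECHAIN_DONORS.get(name, {}))
    if name in STANDARD_AA and name != "PRO":
        donors["N"] = "CA"
    acceptors = set(_SIDECHAIN_ACCEPTORS.get(name, set()))
    if name in STANDARD_AA:
        acceptors |= {"O", "OXT"}
    positive = _POSITIVE_ATOMS.get(name, set())
    negative = _NEGATIVE_ATOMS.get(name, set())
    out = []
    for atom in residue:
        is_donor = atom.name in donors
        is_acceptor = atom.name in acceptors
        if not (is_donor or is_acceptor):
            continue
        antecedent = None
        if is_donor:
            ant_atom = residue.find_atom(donors[atom.name], "*")
            if ant_atom is not None:
                antecedent = np.array([ant_atom.pos.x, ant_atom.pos.y, ant_atom.pos.z])
        out.append(
            {
                "atom": atom.name,
                "pos": np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                "donor": is_donor,
                "acceptor": is_acceptor,
                "antecedent": antecedent,
                "positive": atom.name in positive,
                "negative": atom.name in negative,
            }
        )
    return out


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u, v = a - vertex, b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hbond_ok(d: dict, a: dict, dist: float, criteria: ContactCriteria) -> bool:
    if dist > criteria.hbond_max:
        return False
    if d["antecedent"] is not None:
        if _angle_deg(d["antecedent"], d["pos"], a["pos"]) < criteria.angle_min:
            return False
    return True


def detect_polar_contacts(
    model: StructureModel,
    set_a: Iterable[ResidueKey],
    set_b: Iterable[ResidueKey],
    criteria: ContactCriteria = ContactCriteria(),
) -> ContactNetwork:
    """Hydrogen-bond and ionic contacts between two residue selections.

    A hydrogen bond is a donor-to-acceptor heavy-atom (N/O) pair within
    ``hbond_max`` whose antecedent-donor-acceptor angle is at least
    ``angle_min`` (the angle test is skipped when the antecedent atom is
    absent).  An ionic contact is a charged side-chain nitrogen of
    Arg/Lys/His within ``ionic_max`` of a carboxylate oxygen of Asp/Glu;
    qualifying pairs are labelled ionic, not double-counted as hydrogen
    bonds.  Each unordered atom pair is reported once; by default only the
    closest atom pair per residue pair is kept.
    """
    keys_a, keys_b = list(dict.fromkeys(set_a)), list(dict.fromkeys(set_b))
    if not keys_a or not keys_b:
        raise ValueError("residue selections must be non-empty")

    def atoms_for(keys: list[ResidueKey]) -> list[tuple[ResidueKey, str, dict]]:
        out = []
        for chain, num in keys:
            residue = model.get_residue(chain, num)
            if residue is None:
                continue
            if residue.name not in STANDARD_AA:
                logger.debug("skipping non-standard residue %s %s%d", residue.name, chain, num)
                continue
            for info in _polar_atoms(residue):
                out.append(((chain, num), residue.name, info))
        return out

    atoms_a, atoms_b = atoms_for(keys_a), atoms_for(keys_b)
    records: dict[frozenset, dict] = {}
    for key_a, name_a, ia in atoms_a:
        for key_b, name_b, ib in atoms_b:
            if key_a == key_b:
                continue
            dist = float(np.linalg.norm(ia["pos"] - ib["pos"]))
            if dist > max(criteria.hbond_max, criteria.ionic_max):
                continue
            ionic = (
                dist <= criteria.ionic_max
                and ((ia["positive"] and ib["negative"]) or (ia["negative"] and ib["positive"]))
            )
            hbond = (
                _hbond_ok(ia, ib, dist, criteria) if (ia["donor"] and ib["acceptor"]) else False
            ) or (
                _hbond_ok(ib, ia, dist, criteria) if (ib["donor"] and ia["acceptor"]) else False
            )
            if not (ionic or hbond):
                continue
            pair_key = frozenset([(key_a, ia["atom"]), (key_b, ib["atom"])])
            record = {
                "chain_a": key_a[0], "res_a": key_a[1], "resname_a": name_a, "atom_a": ia["atom"],
                "chain_b": key_b[0], "res_b": key_b[1], "resname_b": name_b, "atom_b": ib["atom"],
                "distance": dist,
                "type": "ionic" if ionic else "hydrogen-bond",
                "helix_pair": "",
            }
            prev = records.get(pair_key)
            if prev is None or dist < prev["distance"]:
                records[pair_key] = record

    edges = pd.DataFrame(list(records.values()), columns=ContactNetwork.EDGE_COLUMNS)
    if not edges.empty and criteria.dedupe == "residue_pair":
        edges["_respair"] = [
            tuple(sorted([(r.chain_a, r.res_a), (r.chain_b, r.res_b)]))
            for r in edges.itertuples()
        ]
        edges = (
            edges.sort_values(["distance"], kind="mergesort")
            .groupby("_respair", as_index=False)
            .first()
            .drop(columns="_respair")
        )
    if not edges.empty:
        edges = edges.sort_values(
            ["chain_a", "res_a", "chain_b", "res_b", "atom_a", "atom_b"], kind="mergesort"
        ).reset_index(drop=True)
    return ContactNetwork(edges=edges[ContactNetwork.EDGE_COLUMNS], criteria=criteria)


@dataclass(frozen=True)
class HelixAnnotation:
    """A named helix given by chain and inclusive author residue range."""

    name: str
    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"helix {self.name}: start {self.start} > end {self.end}")

    def residues(self) -> list[ResidueKey]:
        return [(self.chain, n) for n in range(self.start, self.end + 1)]


@dataclass
class HelixNetworkReport:
    """Inter-helix contact network with per-pair and total counts."""

    network: ContactNetwork
    pair_counts: pd.DataFrame  # helix_pair, residue_pairs, atom_pairs
    residue_pair_total: int
    atom_total: int


def helix_network_report(
    model: StructureModel,
    helices: Sequence[HelixAnnotation],
    criteria: ContactCriteria = ContactCriteria(),
) -> HelixNetworkReport:
    """Polar/ionic contacts between all pairs of the listed helices.

    Only inter-helix residue pairs are considered, so intra-helix backbone
    i,i+4 hydrogen bonds never appear.  Both the residue-pair-level count
    (distinct residue pairs with at least one edge) and the atom-level
    count are reported.
    """
    if len(helices) < 2:
        raise ValueError("need at least 2 helices")
    for i, h1 in enumerate(helices):
        for h2 in helices[i + 1 :]:
            if h1.chain == h2.chain and not (h1.end < h2.start or h2.end < h1.start):
                raise ValueError(f"helix ranges overlap: {h1.name} and {h2.name}")

    frames = []
    counts = []
    for i, h1 in enumerate(helices):
        for h2 in helices[i + 1 :]:
            net = detect_polar_contacts(model, h1.residues(), h2.residues(), criteria)
            label = f"{h1.name}-{h2.name}"
            edges = net.edges.copy()
            edges["helix_pair"] = label
            frames.append(edges)
            counts.append(
                {
                    "helix_pair": label,
                    "residue_pairs": net.residue_pair_count,
                    "atom_pairs": net.atom_count,
                }
            )
    all_edges = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=ContactNetwork.EDGE_COLUMNS
    )
    combined = ContactNetwork(edges=all_edges, criteria=criteria)
    pair_counts = pd.DataFrame(counts)
    return HelixNetworkReport(
        network=combined,
        pair_counts=pair_counts,
        residue_pair_total=combined.residue_pair_count,
        atom_total=combined.atom_count,
    )


def contact_count_grid(
    model: StructureModel,
    helices: Sequence[HelixAnnotation],
    hbond_max_values: Sequence[float],
    ionic_max_values: Sequence[float],
    angle_min: float = 90.0,
    dedupe: str = "residue_pair",
) -> pd.DataFrame:
    """Inter-helix contact counts over a grid of distance cutoffs.

    The geometric definition of a 'designated' hydrogen bond varies between
    tools, so reproduction of a published count is reported across a cutoff
    grid rather than asserted at a single default.
    """
    rows = []
    for h in hbond_max_values:
        for i in ionic_max_values:
            crit = ContactCriteria(hbond_max=h, ionic_max=i, angle_min=angle_min, dedupe=dedupe)
            rep = helix_network_report(model, helices, crit)
            rows.append(
                {
                    "hbond_max": h,
                    "ionic_max": i,
                    "residue_pairs": rep.residue_pair_total,
                    "atom_pairs": rep.atom_total,
                }
            )
    return pd.DataFrame(rows)


def map_scores_to_structure(
    model: StructureModel,
    profile,
    chain: str,
    scale: float = 100.0,
    sentinel: float = -1.0,
) -> tuple[StructureModel, list[int]]:
    """Write per-site scores into the B-factor column of a copy of the model.

    Residue r's atoms get B = scale * S(r), clamped to [0, 999.99] (PDB
    column width).  Residues without a defined profile value get
    ``sentinel`` and are returned for reporting.  Intended for rendering
    conservation on the structure (e.g. colour by B-factor).
    """
    if chain not in model.chain_names():
        raise KeyError(f"chain {chain!r} not in model")
    scores: dict[int, float] = {}
    for site, s in zip(profile.site_numbers, profile.entropy):
        if not np.isnan(s):
            scores[int(site)] = float(s)
    painted = model.copy()
    missing: list[int] = []
    for ch in painted.model:
        if ch.name != chain:
            continue
        for residue in ch:
            if residue.seqid.num in scores:
                b = float(np.clip(scale * scores[residue.seqid.num], 0.0, 999.99))
            else:
                b = sentinel
                missing.append(residue.seqid.num)
            for atom in residue:
                atom.b_iso = b
    if missing:
        logger.warning("%d residues in chain %s had no profile value", len(missing), chain)
    return painted, missing


def mutation_overlap_report(
    network: ContactNetwork,
    profile,
    cmt_sites: Sequence[int],
    s_max: float = 0.1,
    chain: str | None = None,
    focus_residues: Sequence[int] | None = None,
) -> dict:
    """Classify residues by disease-mutation and conservation membership.

    Every residue appearing in the contact network, the mutation-site list
    or the conserved-site list (profile entropy <= ``s_max``) is classed as
    ``both``, ``cmt-only``, ``conserved-only`` or ``neither``.  When
    ``focus_residues`` is given (e.g. the α6-α7 loop), the residues
    contacting that segment in the network are listed with their classes.
    """
    conserved = {
        int(site)
        for site, s in zip(profile.site_numbers, profile.entropy)
        if not np.isnan(s) and s <= s_max
    }
    cmt = {int(r) for r in cmt_sites}

    network_residues = network.residues()
    if chain is not None:
        network_residues = {k for k in network_residues if k[0] == chain}
    residue_numbers = sorted({num for _, num in network_residues} | cmt | conserved)

    def classify(num: int) -> str:
        in_cmt, in_cons = num in cmt, num in conserved
        if in_cmt and in_cons:
            return "both"
        if in_cmt:
            return "cmt-only"
        if in_cons:
            return "conserved-only"
        return "neither"

    table = pd.DataFrame(
        {
            "residue": residue_numbers,
            "cmt_site": [n in cmt for n in residue_numbers],
            "conserved": [n in conserved for n in residue_numbers],
            "class": [classify(n) for n in residue_numbers],
            "in_network": [
                any(num == n for _, num in network_residues) for n in residue_numbers
            ],
        }
    )

    focus_contacts = None
    if focus_residues is not None:
        focus = set(int(r) for r in focus_residues)
        partners: set[int] = set()
        for r in network.edges.itertuples():
            a, b = r.res_a, r.res_b
            if a in focus and b not in focus:
                partners.add(b)
            elif b in focus and a not in focus:
                partners.add(a)
        focus_contacts = pd.DataFrame(
            {
                "residue": sorted(partners),
                "class": [classify(n) for n in sorted(partners)],
            }
        )
    return {"table": table, "focus_contacts": focus_contacts}
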