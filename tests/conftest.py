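"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import gemmi
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from famcons.sequence_io import ProjectedAlignment, SequenceRecord
from famcons.structure import StructureModel
from famcons import synthetic as syn


def make_alignment(columns: list[str], ids: list[str] | None = None,
                   row_groups=None) -> ProjectedAlignment:
    """Build a projected alignment from per-column strings (one char per row)."""
    n_rows = len(columns[0])
    assert all(len(c) == n_rows for c in columns)
    mat = np.array([[col[r] for col in columns] for r in range(n_rows)], dtype="<U1")
    if ids is None:
        ids = [f"s{i}" for i in range(n_rows)]
    return ProjectedAlignment(
        reference_id=ids[0],
        ids=ids,
        site_numbers=list(range(1, len(columns) + 1)),
        columns=mat,
        row_groups=row_groups,
    )


def records_from(rows: dict[str, str], descriptions: dict[str, str] | None = None):
    descriptions = descriptions or {}
    return [
        SequenceRecord(id=k, description=descriptions.get(k, k), residues=v)
        for k, v in rows.items()
    ]


@pytest.fixture
def fasta_file(tmp_path):
    def write(text: str, name: str = "seqs.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p
    return write


def build_model(residues) -> StructureModel:
    """Assemble a StructureModel from (chain, resnum, resname, atoms) tuples,
    atoms being (name, element, (x, y, z))."""
    st = gemmi.Structure()
    st.name = "fixture"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for chain_name, num, resname, atoms in residues:
        ch = chains.setdefault(chain_name, gemmi.Chain(chain_name))
        r = gemmi.Residue()
        r.name = resname
        r.seqid = gemmi.SeqId(num, " ")
        r.het_flag = "A"
        for name, element, xyz in atoms:
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(element)
            a.pos = gemmi.Position(*xyz)
            a.occ = 1.0
            a.b_iso = 0.0
            r.add_atom(a)
        ch.add_residue(r)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    return StructureModel(st)


def engineered_two_helix_model():
    """Two ideal helices 12 A apart bridged by exactly 3 engineered
    hydroxyl-hydroxyl hydrogen bonds (Ser OG pairs placed in the gap).

    Returns (model, helix residue ranges, expected residue pairs).
    """
    model = syn.generate_toy_structure(
        syn.ToyStructureSpec(
            helices=(
                syn.HelixPlacement(10, origin=(0.0, 0.0, 0.0)),
                syn.HelixPlacement(10, origin=(12.0, 0.0, 0.0)),
            )
        )
    )
    pairs = [(2, 12), (5, 15), (8, 18)]
    for donor_res, acceptor_res in pairs:
        for num in (donor_res, acceptor_res):
            model.get_residue("A", num).name = "SER"
        ca_d = model.ca_positions([("A", donor_res)])[("A", donor_res)]
        ca_a = model.ca_positions([("A", acceptor_res)])[("A", acceptor_res)]
        mid_y, mid_z = (ca_d[1] + ca_a[1]) / 2, (ca_d[2] + ca_a[2]) / 2
        syn.add_pseudo_atom(model, "A", donor_res, "OG", (4.6, mid_y, mid_z), "O")
        syn.add_pseudo_atom(model, "A", acceptor_res, "OG", (7.4, mid_y, mid_z), "O")
    return model, [(1, 10), (11, 20)], [tuple(sorted(p)) for p in pairs]
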