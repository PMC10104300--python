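"""End-to-end orchestration from a single declarative TOML config.

Two pipelines compose the library modules:

* the sequence pipeline — group sequences by annotation, project the MSA
  onto the reference, report conserved sites per group, compute the
  bidirectional KL divergence table between two groups, and reduce the
  set to k evenly spread representatives;
* the structure pipeline — extract the inter-helix contact network,
  profile per-variant Cα deviations against wild type, paint conservation
  into the B-factor column, and classify mutation/conservation overlap.

Every run writes a manifest recording the config hash, input checksums and
package version, so outputs are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

import famcons
from famcons import conservation, representatives, sequence_io, structure

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when the run configuration is invalid."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run configuration (see the shipped gdap1.toml for keys)."""

    msa: Path | None = None
    reference: str | None = None
    group_rules: list[tuple[str, list[str]]] = field(default_factory=list)
    drop_patterns: list[str] = field(default_factory=lambda: ["hypothetical", "putative"])
    group1: str | None = None
    group2: str | None = None
    s_conserved: float = 0.2
    s_highly: float = 0.1
    frac_min: float = 0.7
    pseudocount: float = 0.5
    reduce_k: int | None = None
    wildtype: Path | None = None
    variants: list[Path] = field(default_factory=list)
    chain: str = "A"
    helices: list[structure.HelixAnnotation] = field(default_factory=list)
    cmt_sites: list[int] = field(default_factory=list)
    focus_residues: list[int] = field(default_factory=list)
    contact_criteria: structure.ContactCriteria = field(default_factory=structure.ContactCriteria)
    out_dir: Path = Path("famcons_out")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("s_conserved", "s_highly", "frac_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"threshold {name} must be in (0, 1], got {v}")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")


def default_annotation() -> dict[str, Any]:
    """The shipped GDAP1 helix/mutation annotation as a plain dict."""
    path = Path(__file__).parent / "data" / "gdap1.toml"
    return tomllib.loads(path.read_text())


def default_helices() -> list[structure.HelixAnnotation]:
    return [
        structure.HelixAnnotation(h["name"], h["chain"], h["start"], h["end"])
        for h in default_annotation()["helices"]
    ]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        raw = tomllib.loads(path.read_text())
    except (OSError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc

    base = path.parent

    def respath(p: str | None) -> Path | None:
        return (base / p) if p else None

    inputs = raw.get("inputs", {})
    groups = raw.get("groups", {})
    thresholds = raw.get("thresholds", {})
    contacts = raw.get("contacts", {})
    structures = raw.get("structures", {})
    cmt = raw.get("cmt", {})
    output = raw.get("output", {})

    rules = [(r["label"], list(r["patterns"])) for r in groups.get("rules", [])]
    helices = [
        structure.HelixAnnotation(h["name"], h["chain"], h["start"], h["end"])
        for h in raw.get("helices", [])
    ]
    loop = raw.get("loop_a6_a7", {})
    focus = list(cmt.get("focus", []))
    if not focus and loop:
        focus = list(range(loop["start"], loop["end"] + 1))

    cfg = RunConfig(
        msa=respath(inputs.get("msa")),
        reference=inputs.get("reference"),
        group_rules=rules,
        drop_patterns=list(groups.get("drop", ["hypothetical", "putative"])),
        group1=groups.get("group1"),
        group2=groups.get("group2"),
        s_conserved=thresholds.get("s_conserved", 0.2),
        s_highly=thresholds.get("s_highly", 0.1),
        frac_min=thresholds.get("frac_min", 0.7),
        pseudocount=thresholds.get("pseudocount", 0.5),
        reduce_k=raw.get("reduce", {}).get("k"),
        wildtype=respath(structures.get("wildtype")),
        variants=[base / p for p in structures.get("variants", [])],
        chain=structures.get("chain", "A"),
        helices=helices,
        cmt_sites=list(cmt.get("sites", [])),
        focus_residues=focus,
        contact_criteria=structure.ContactCriteria(
            hbond_max=contacts.get("hbond_max", 3.5),
            ionic_max=contacts.get("ionic_max", 4.0),
            angle_min=contacts.get("angle_min", 90.0),
            dedupe=contacts.get("dedupe", "residue_pair"),
        ),
        out_dir=base / output.get("dir", "famcons_out"),
        seed=int(output.get("seed", 0)),
    )
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, config_repr: str, inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "famcons_version": famcons.__version__,
        "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
        "inputs": {str(p): _sha256(p) for p in inputs if p and p.exists()},
        "outputs": [str(p) for p in outputs],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_sequence_pipeline(config: RunConfig) -> dict[str, Any]:
    """Group -> project -> entropy/KL -> reduce; writes a report bundle."""
    if config.msa is None or config.reference is None:
        raise ConfigError("sequence pipeline needs inputs.msa and inputs.reference")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    results: dict[str, Any] = {}

    try:
        records = sequence_io.read_fasta(config.msa)
    except sequence_io.FastaParseError as exc:
        raise PipelineError("read", str(exc)) from exc

    row_groups: list[str | None] | None = None
    grouping = None
    if config.group_rules:
        try:
            grouping = sequence_io.assign_groups(records, config.group_rules, config.drop_patterns)
        except ValueError as exc:
            raise PipelineError("group", str(exc)) from exc
        by_id: dict[str, str] = {}
        for g in grouping.groups:
            for m in g.members:
                by_id[m] = g.label
        row_groups = [by_id.get(r.id) for r in records]
        results["grouping"] = {g.label: len(g) for g in grouping.groups}
        results["dropped"] = grouping.dropped
        logger.info("groups: %s (dropped %d, unmatched %d)",
                    results["grouping"], len(grouping.dropped), len(grouping.unmatched))

    try:
        projection = sequence_io.project_to_reference(records, config.reference, row_groups)
    except (KeyError, ValueError) as exc:
        raise PipelineError("project", str(exc)) from exc
    proj_path = out / "projection.fasta"
    sequence_io.write_fasta(sequence_io.alignment_to_records(projection), proj_path)
    outputs.append(proj_path)
    results["projection"] = projection

    # per-group conserved-site tables
    analysed_groups = [g for g, _ in config.group_rules] if config.group_rules else [None]
    for label in analysed_groups:
        rows = projection.rows_of_group(label) if label else None
        if rows == []:
            logger.warning("group %s has no rows in the alignment; skipped", label)
            continue
        profile = conservation.entropy_profile(projection, rows)
        table = conservation.conserved_sites(profile, config.s_highly, config.frac_min)
        name = f"conserved_{label or 'all'}.tsv"
        table.to_csv(out / name, sep="\t", index=False, float_format="%.4f")
        outputs.append(out / name)
        results[f"profile_{label or 'all'}"] = profile
        results[f"conserved_{label or 'all'}"] = table

    if config.group1 and config.group2:
        try:
            rows1 = projection.rows_of_group(config.group1)
            rows2 = projection.rows_of_group(config.group2)
            div = conservation.divergence_profile(
                projection, rows1, rows2, config.pseudocount,
                group_labels=(config.group1, config.group2),
            )
        except ValueError as exc:
            raise PipelineError("divergence", str(exc)) from exc
        ranked = div.ranked_table(config.s_conserved)
        div_path = out / "divergence.tsv"
        ranked.to_csv(div_path, sep="\t", index=False, float_format="%.4f")
        outputs.append(div_path)
        results["divergence"] = div

    if config.reduce_k:
        try:
            matrix = representatives.pairwise_identity_matrix(records)
            retained = representatives.select_representatives(matrix, config.reduce_k)
        except ValueError as exc:
            raise PipelineError("reduce", str(exc)) from exc
        keep = {r.id for r in records} & set(retained)
        reduced = [r for r in records if r.id in keep]
        red_path = out / "representatives.fasta"
        sequence_io.write_fasta(reduced, red_path)
        outputs.append(red_path)
        results["representatives"] = retained

    _write_manifest(out, repr(config), [config.msa], outputs)
    return results


def run_structure_pipeline(config: RunConfig, profile=None) -> dict[str, Any]:
    """Networks -> deviations -> painting -> mutation overlap report bundle."""
    if config.wildtype is None:
        raise ConfigError("structure pipeline needs structures.wildtype")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    results: dict[str, Any] = {}

    try:
        wildtype = structure.read_structure(config.wildtype)
    except structure.StructureError as exc:
        raise PipelineError("read-structure", str(exc)) from exc

    network = None
    if len(config.helices) >= 2:
        try:
            report = structure.helix_network_report(wildtype, config.helices, config.contact_criteria)
        except ValueError as exc:
            raise PipelineError("network", str(exc)) from exc
        network = report.network
        net_path = out / "contact_network.tsv"
        network.to_tsv(net_path)
        counts_path = out / "contact_counts.tsv"
        report.pair_counts.to_csv(counts_path, sep="\t", index=False)
        outputs += [net_path, counts_path]
        results["network_report"] = report
        logger.info("inter-helix contacts: %d residue pairs, %d atom pairs",
                    report.residue_pair_total, report.atom_total)

    network_keys = network.residues() if network is not None else None
    for variant_path in config.variants:
        try:
            variant = structure.read_structure(variant_path)
            dev = structure.ca_deviation_profile(
                variant, wildtype, report_selection=network_keys
            )
        except (structure.StructureError, ValueError) as exc:
            raise PipelineError("deviation", str(exc)) from exc
        name = f"deviation_{variant_path.stem}.tsv"
        dev.to_tsv(out / name)
        outputs.append(out / name)
        results[f"deviation_{variant_path.stem}"] = dev

    if profile is not None:
        painted, missing = structure.map_scores_to_structure(wildtype, profile, config.chain)
        paint_path = out / "conservation_painted.pdb"
        painted.write_pdb(paint_path)
        outputs.append(paint_path)
        results["painted_missing_sites"] = missing
        if config.cmt_sites and network is not None:
            overlap = structure.mutation_overlap_report(
                network, profile, config.cmt_sites,
                s_max=config.s_highly, chain=config.chain,
                focus_residues=config.focus_residues or None,
            )
            ov_path = out / "mutation_overlap.tsv"
            overlap["table"].to_csv(ov_path, sep="\t", index=False)
            outputs.append(ov_path)
            results["overlap"] = overlap

    _write_manifest(out, repr(config), [config.wildtype, *config.variants], outputs)
    return results
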