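"""End-to-end analysis runs with reproducible manifests.

A run stitches the stages together: discriminative motif search on the
labeled enzyme panel, the positives-only shared-motif comparison of the
accessory proteins, ortholog identity statistics with the binder versus
non-binder rank test, the identity-distance neighbor-joining tree with a
binder-clade check, and (when tables are provided) binding quantification
and lethal-fraction stages.  Each run emits a manifest — config echo,
input checksums, package version, seed, per-stage warnings — such that
re-running from the same manifest inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .conservation import (
    identity_distance_matrix,
    is_clade,
    mann_whitney_u,
    neighbor_joining,
    ortholog_identity_stats,
    tree_to_newick,
)
from .io import (
    AnalysisConfig,
    LabeledSequenceSet,
    ProteinRecord,
    fasta_bytes,
    write_report,
)
from .motifs import MotifReport, find_discriminative_motifs, positives_shared_motifs


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    config: dict
    input_checksums: dict[str, str]
    version: str
    seed: int
    stages: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _checksum(records: Sequence[ProteinRecord]) -> str:
    return hashlib.sha256(fasta_bytes(records)).hexdigest()


def _motif_report_dict(report: MotifReport) -> dict:
    return {
        "mode": report.mode,
        "n_positives": report.n_positives,
        "n_negatives": report.n_negatives,
        "min_len": report.min_len,
        "motifs": [
            {
                "string": m.string,
                "length": len(m),
                "maximal": m.maximal,
                "occurrences": {k: list(v) for k, v in m.occurrences.items()},
            }
            for m in report.motifs
        ],
        "maximal": [m.string for m in report.maximal],
    }


def run_panel_analysis(
    enzyme_set: LabeledSequenceSet,
    ortholog_pairs: Sequence[tuple[ProteinRecord, ProteinRecord]] | None = None,
    accessory_records: Sequence[ProteinRecord] | None = None,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
    binder_ids: Sequence[str] | None = None,
) -> dict:
    """Run the sequence stages of the study analysis.

    Returns a dict with the discriminative motif report, the accessory
    shared-motif report, ortholog identity statistics plus the
    Mann-Whitney comparison of binder versus non-binder identities, the
    neighbor-joining tree (newick) and the observed binder-clade status,
    and the run manifest.  When *out_dir* is given, reports are also
    written as deterministic JSON/TSV/newick files.
    """
    config = config or AnalysisConfig()
    manifest = RunManifest(
        config=asdict(config),
        input_checksums={"enzymes": _checksum(enzyme_set.records)},
        version=__version__,
        seed=config.seed,
    )
    results: dict = {"manifest": manifest}

    # 1. discriminative motifs on the labeled enzyme panel
    motif_report = find_discriminative_motifs(enzyme_set, config.motif_min_len)
    results["motifs"] = motif_report
    manifest.stages.append("motifs")

    # 2. positives-only shared motifs across the accessory-protein family
    if accessory_records:
        shared = positives_shared_motifs(accessory_records, config.motif_min_len)
        results["shared_motifs"] = shared
        manifest.input_checksums["accessory"] = _checksum(accessory_records)
        manifest.stages.append("shared_motifs")

    # 3. ortholog identity panel + binder/non-binder rank test
    if ortholog_pairs:
        stats = ortholog_identity_stats(ortholog_pairs, config)
        binder_ids = set(binder_ids or (r.id for r in enzyme_set.binders))
        binder_idents = [
            ident
            for (a, _), ident in zip(ortholog_pairs, stats["identities"])
            if a.id in binder_ids
        ]
        nonbinder_idents = [
            ident
            for (a, _), ident in zip(ortholog_pairs, stats["identities"])
            if a.id not in binder_ids
        ]
        mwu = (
            mann_whitney_u(binder_idents, nonbinder_idents)
            if binder_idents and nonbinder_idents
            else None
        )
        results["ortholog_identity"] = {
            **stats,
            "binder_mean": (
                sum(binder_idents) / len(binder_idents) if binder_idents else None
            ),
            "nonbinder_mean": (
                sum(nonbinder_idents) / len(nonbinder_idents)
                if nonbinder_idents
                else None
            ),
            "mann_whitney": mwu,
        }
        manifest.stages.append("ortholog_identity")

    # 4. identity-distance neighbor-joining tree of the enzyme panel
    analyzed = enzyme_set.binders + enzyme_set.nonbinders
    if len(analyzed) >= 3:
        dm = identity_distance_matrix(analyzed, config)
        tree = neighbor_joining(dm)
        binder_set = {r.id for r in enzyme_set.binders}
        results["tree"] = {
            "newick": tree_to_newick(tree),
            "binder_clade": is_clade(tree, binder_set),
            "binders": sorted(binder_set),
        }
        results["_tree_object"] = tree
        manifest.stages.append("tree")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(_motif_report_dict(motif_report), out_dir / "motifs.json")
        if "shared_motifs" in results:
            write_report(
                _motif_report_dict(results["shared_motifs"]),
                out_dir / "shared_motifs.json",
            )
        if "ortholog_identity" in results:
            write_report(
                results["ortholog_identity"], out_dir / "ortholog_identity.json"
            )
        if "tree" in results:
            (out_dir / "tree.nwk").write_text(results["tree"]["newick"] + "\n")
        write_report(asdict(manifest), out_dir / "manifest.json")
    return results


def run_default_panel(
    config: AnalysisConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Run the full sequence analysis on the synthetic stand-in panel."""
    from .synthetic_panel import build_panel

    panel = build_panel()
    return run_panel_analysis(
        enzyme_set=panel.mouse,
        ortholog_pairs=panel.ortholog_pairs,
        accessory_records=[panel.golga7, panel.golga7b],
        config=config,
        out_dir=out_dir,
    )
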