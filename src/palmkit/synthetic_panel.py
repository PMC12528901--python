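"""Synthetic stand-in sequence panel for the ZDHHC/GOLGA7 study system.

This module generates *synthetic* protein sequences — random backgrounds
with planted structure — that stand in for the real UniProt entries of
the 23 mouse Zdhhc-family enzymes, their human orthologs, and the
accessory proteins GOLGA7/GOLGA7B.  Record ids reuse the real accession
numbers so the panel is drop-in compatible with label tables and report
formats, but the sequences themselves are not the database entries: they
reproduce the features the downstream analyses measure, namely

* the RNYR motif planted in all six GOLGA7-binding enzymes, at residues
  144-147 of the Zdhhc5 stand-in, and absent from all non-binders;
* the near-miss RNFR at residues 152-155 of the Zdhhc19 stand-in;
* a per-gene mouse-human percent identity (substitution-only orthologs)
  fixed so the panel reproduces the published summary statistics:
  median 93, range 60-99, binder mean 94, non-binder mean 89, Zdhhc5 98;
* the RDYS motif at residues 16-19 of the GOLGA7 stand-in and 25-28 of
  the GOLGA7B stand-in (which carries a 9-residue N-terminal extension),
  with flanking mismatches so RDYS itself is the maximal shared motif,
  and a planted GOLGA7/GOLGA7B identity of 79% (global, matches/columns).

Everything is a pure function of the seed; the default seed is part of
the panel definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LabeledSequenceSet, ProteinRecord
from .motifs import locate_motif
from .simulate import AA20, mutate_sequence

#: Seed that defines the default stand-in panel.
DEFAULT_PANEL_SEED = 7

RNYR = "RNYR"
RNFR = "RNFR"
RDYS = "RDYS"

#: Gene -> (mouse accession, human accession, stand-in length,
#:          planted mouse-human percent identity).  The human counterpart
#: of Zdhhc25 is not part of the published accession list; a synthetic id
#: marks it.  Identities were fixed once from the published summary
#: statistics for the binder and non-binder groups.
ZDHHC_PANEL: dict[str, tuple[str, str, int, int]] = {
    "Zdhhc1": ("Q8R0N9", "Q8WTX9", 485, 95),
    "Zdhhc2": ("P59267", "Q9UIJ5", 367, 97),
    "Zdhhc3": ("Q8R173", "Q9NYG2", 299, 99),
    "Zdhhc4": ("Q9D6H5", "Q9NPG8", 345, 88),
    "Zdhhc5": ("Q8VDZ4", "Q9C0B5", 715, 98),
    "Zdhhc6": ("Q9CPV7", "Q9H6R6", 413, 95),
    "Zdhhc7": ("Q91WU6", "Q9NXF8", 310, 96),
    "Zdhhc8": ("Q5Y5T5", "Q9ULC8", 765, 96),
    "Zdhhc9": ("P59268", "Q9Y397", 364, 97),
    "Zdhhc11": ("Q14AK4", "Q9H8X9", 412, 60),
    "Zdhhc12": ("Q8VC90", "Q96GR4", 267, 84),
    "Zdhhc13": ("Q9CWU2", "Q8IUH4", 622, 93),
    "Zdhhc14": ("Q8BQQ1", "Q8IZN3", 488, 86),
    "Zdhhc15": ("Q8BGJ0", "Q96MV8", 337, 94),
    "Zdhhc16": ("Q9ESG8", "Q969W1", 377, 92),
    "Zdhhc17": ("Q80TN5", "Q8IUH5", 632, 94),
    "Zdhhc18": ("Q5Y5T2", "Q9NUE0", 388, 92),
    "Zdhhc19": ("Q810M5", "Q8WVZ1", 309, 80),
    "Zdhhc20": ("Q5Y5T1", "Q5W0Z9", 380, 93),
    "Zdhhc21": ("Q9D270", "Q8IVQ6", 281, 91),
    "Zdhhc23": ("Q5Y5T3", "Q8IYP9", 409, 86),
    "Zdhhc24": ("Q6IR37", "Q6UX98", 284, 81),
    "Zdhhc25": ("Q810M4", "SYN-H25", 280, 90),
}

#: The six enzymes that recover endogenous GOLGA7 in the co-IP screen of
#: ZDHHC5-knockout cells; this labeling drives the motif search.
BINDERS = ("Zdhhc1", "Zdhhc5", "Zdhhc8", "Zdhhc9", "Zdhhc14", "Zdhhc18")

#: Alternate labeling matching the interaction pattern seen in unmodified
#: control cells (Zdhhc1 drops out, Zdhhc14 strengthens).  Provided to
#: explore the sensitivity of the motif set to the labeling; no specific
#: output is asserted for it.
CONTROL_CELL_BINDERS = ("Zdhhc5", "Zdhhc8", "Zdhhc9", "Zdhhc14", "Zdhhc18")


def control_cell_labels(panel: "SyntheticPanel") -> dict[str, str]:
    """Label map for the control-cell binder pattern over the panel ids."""
    return {
        rec.id: (
            "binder"
            if panel.gene_of[rec.id] in CONTROL_CELL_BINDERS
            else "nonbinder"
        )
        for rec in panel.mouse.records
    }

#: 1-based RNYR start positions planted in the binder stand-ins.
RNYR_POSITIONS = {
    "Zdhhc1": 152,
    "Zdhhc5": 144,
    "Zdhhc8": 161,
    "Zdhhc9": 138,
    "Zdhhc14": 170,
    "Zdhhc18": 149,
}

#: 1-based RNFR start in the Zdhhc19 stand-in (the near-miss non-binder).
RNFR_POSITION_ZDHHC19 = 152

GOLGA7_ACCESSION = "Q7Z5G4"
GOLGA7B_ID = "SYN-GOLGA7B"  # cDNA-only in the source records; stand-in id
GOLGA7_LENGTH = 137
GOLGA7B_EXTENSION = 9  # N-terminal residues absent from GOLGA7
RDYS_POSITION_GOLGA7 = 16
RDYS_POSITION_GOLGA7B = RDYS_POSITION_GOLGA7 + GOLGA7B_EXTENSION
#: Substitutions between the GOLGA7/GOLGA7B stand-in cores, fixed so that
#: global matches/columns identity is 115/146 = 78.8 ~ 79%.
GOLGA7B_N_SUBSTITUTIONS = 22

_BUDGET = 5000


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _background_without(
    rng: np.random.Generator, length: int, forbidden: tuple[str, ...]
) -> str:
    for _ in range(_BUDGET):
        seq = _random_seq(rng, length)
        if all(f not in seq for f in forbidden):
            return seq
    raise RuntimeError("rejection budget exhausted generating background")


def _splice(seq: str, motif: str, pos1: int) -> str:
    """Overwrite *seq* with *motif* at 1-based position *pos1* (length kept)."""
    i = pos1 - 1
    return seq[:i] + motif + seq[i + len(motif) :]


@dataclass(frozen=True)
class SyntheticPanel:
    """The generated stand-in panel and its planted ground truth."""

    mouse: LabeledSequenceSet
    human: tuple[ProteinRecord, ...]
    ortholog_pairs: tuple[tuple[ProteinRecord, ProteinRecord], ...]
    golga7: ProteinRecord
    golga7b: ProteinRecord
    erf4: ProteinRecord
    planted_identity: dict[str, float]
    gene_of: dict[str, str]
    seed: int

    @property
    def binder_pairs(self):
        return tuple(
            (a, b)
            for (a, b) in self.ortholog_pairs
            if self.gene_of[a.id] in BINDERS
        )

    @property
    def nonbinder_pairs(self):
        return tuple(
            (a, b)
            for (a, b) in self.ortholog_pairs
            if self.gene_of[a.id] not in BINDERS
        )


def build_panel(seed: int = DEFAULT_PANEL_SEED) -> SyntheticPanel:
    """Generate the full synthetic stand-in panel (pure function of seed)."""
    rng = np.random.default_rng(seed)
    mouse_records: list[ProteinRecord] = []
    human_records: list[ProteinRecord] = []
    pairs: list[tuple[ProteinRecord, ProteinRecord]] = []
    labels: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    planted_identity: dict[str, float] = {}

    for gene, (macc, hacc, length, identity) in ZDHHC_PANEL.items():
        is_binder = gene in BINDERS
        for _ in range(_BUDGET):
            seq = _background_without(rng, length, (RNYR,))
            if is_binder:
                seq = _splice(seq, RNYR, RNYR_POSITIONS[gene])
                if len(locate_motif(seq, RNYR)) != 1:
                    continue
            elif gene == "Zdhhc19":
                seq = _splice(seq, RNFR, RNFR_POSITION_ZDHHC19)
                if RNYR in seq or len(locate_motif(seq, RNFR)) != 1:
                    continue
            break
        else:
            raise RuntimeError(f"could not generate stand-in for {gene}")
        mouse = ProteinRecord(
            id=macc, sequence=seq, name=f"{gene} synthetic stand-in",
            species="Mus musculus (synthetic)",
        )
        n_sub = round(length * (1 - identity / 100))
        human_seq = mutate_sequence(seq, n_sub, rng)
        human = ProteinRecord(
            id=hacc, sequence=human_seq,
            name=f"{gene} human ortholog synthetic stand-in",
            species="Homo sapiens (synthetic)",
        )
        mouse_records.append(mouse)
        human_records.append(human)
        pairs.append((mouse, human))
        labels[macc] = "binder" if is_binder else "nonbinder"
        gene_of[macc] = gene_of[hacc] = gene
        planted_identity[gene] = 100.0 * (length - n_sub) / length

    golga7, golga7b = _build_golga_pair(rng)
    erf4 = _build_erf4(rng)
    return SyntheticPanel(
        mouse=LabeledSequenceSet(records=tuple(mouse_records), labels=labels),
        human=tuple(human_records),
        ortholog_pairs=tuple(pairs),
        golga7=golga7,
        golga7b=golga7b,
        erf4=erf4,
        planted_identity=planted_identity,
        gene_of=gene_of,
        seed=seed,
    )


def _build_golga_pair(
    rng: np.random.Generator,
) -> tuple[ProteinRecord, ProteinRecord]:
    """GOLGA7/GOLGA7B stand-ins sharing RDYS as their maximal common motif."""
    core_rdys0 = RDYS_POSITION_GOLGA7 - 1  # 0-based within the core
    for _ in range(_BUDGET):
        core = _background_without(rng, GOLGA7_LENGTH, (RDYS,))
        core = _splice(core, RDYS, RDYS_POSITION_GOLGA7)
        if len(locate_motif(core, RDYS)) != 1:
            continue
        # mutate the paralog core, forcing mismatches immediately flanking
        # RDYS so the motif itself (not an extension) is maximal
        flank_left, flank_right = core_rdys0 - 1, core_rdys0 + len(RDYS)
        body = mutate_sequence(
            core,
            GOLGA7B_N_SUBSTITUTIONS - 2,
            rng,
            protected=(flank_left, flank_right + 1),
        )
        body = _force_substitution(body, flank_left, rng)
        body = _force_substitution(body, flank_right, rng)
        ext = _random_seq(rng, GOLGA7B_EXTENSION)
        paralog = ext + body
        if len(locate_motif(paralog, RDYS)) != 1:
            continue
        if RDYS not in paralog[RDYS_POSITION_GOLGA7B - 1 :]:
            continue
        golga7 = ProteinRecord(
            id=GOLGA7_ACCESSION, sequence=core,
            name="GOLGA7 synthetic stand-in", species="Homo sapiens (synthetic)",
        )
        golga7b = ProteinRecord(
            id=GOLGA7B_ID, sequence=paralog,
            name="GOLGA7B synthetic stand-in", species="Homo sapiens (synthetic)",
        )
        return golga7, golga7b
    raise RuntimeError("could not generate GOLGA7/GOLGA7B stand-ins")


def _force_substitution(seq: str, i: int, rng: np.random.Generator) -> str:
    choices = [c for c in AA20 if c != seq[i]]
    return seq[:i] + str(rng.choice(choices)) + seq[i + 1 :]


def _build_erf4(rng: np.random.Generator) -> ProteinRecord:
    """A distant accessory-protein stand-in carrying RDYS once."""
    length, pos = 227, 41
    for _ in range(_BUDGET):
        seq = _splice(_background_without(rng, length, (RDYS,)), RDYS, pos)
        if len(locate_motif(seq, RDYS)) == 1:
            return ProteinRecord(
                id="SYN-ERF4", sequence=seq,
                name="Erf4 synthetic stand-in",
                species="Schizosaccharomyces pombe (synthetic)",
            )
    raise RuntimeError("could not generate Erf4 stand-in")
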