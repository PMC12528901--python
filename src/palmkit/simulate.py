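"""Seeded synthetic-data generators with recorded ground truth.

Every input class the pipeline consumes can be emulated here: labeled
sequence families with a planted discriminative motif and near-miss
decoys, ortholog pairs of controlled percent identity, additive distance
matrices from random trees (a neighbor-joining oracle), noisy co-IP band
tables from known binding fractions, and cell-death count streams from a
minimal growth/death model with a closed-form lethal fraction.  All
generators are pure functions of their spec and seed: identical inputs
produce identical outputs, and each returns a ground-truth record
sufficient to score the corresponding analysis stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio.tree import TreeNode

from .binding import BandMeasurement, CoIPLane, net_band_intensity
from .conservation import DistanceMatrix
from .death import DeathTimecourse, DeathTimepoint
from .io import LabeledSequenceSet, ProteinRecord

#: The 20 standard amino acids.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

_REJECTION_BUDGET = 2000


@dataclass(frozen=True)
class MotifFamilySpec:
    """A binder/non-binder sequence family with one planted motif.

    Defaults mirror the study panel shape: 6 positives versus 17
    negatives, one negative carrying a single-substitution decoy (the
    near-miss pattern), uniform flank composition over the 20 standard
    residues.
    """

    motif: str = "RNYR"
    n_positives: int = 6
    n_negatives: int = 17
    length: int = 300
    alphabet: str = AA20
    n_decoy_negatives: int = 1
    decoy: str | None = None  # default: one substitution, seeded choice
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.motif) < 2:
            raise ValueError("motif must have length >= 2")
        if len(self.motif) >= self.length:
            raise ValueError("motif must be shorter than the sequence length")
        if self.decoy is not None:
            if len(self.decoy) != len(self.motif) or self.decoy == self.motif:
                raise ValueError("decoy must differ from motif in >= 1 position")
        if self.n_decoy_negatives > self.n_negatives:
            raise ValueError("more decoy negatives than negatives")


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def simulate_motif_family(
    spec: MotifFamilySpec,
) -> tuple[LabeledSequenceSet, dict]:
    """Generate a labeled family with the motif planted once per positive.

    Positives contain the motif exactly once at a recorded position; no
    negative contains it (rejection-sampled); the chosen number of
    negatives carry the decoy instead.  Raises if the rejection budget is
    exhausted (motif too short for the alphabet/length combination).
    """
    rng = np.random.default_rng(spec.seed)
    motif = spec.motif
    decoy = spec.decoy
    if decoy is None and spec.n_decoy_negatives > 0:
        pos = int(rng.integers(len(motif)))
        choices = [c for c in spec.alphabet if c != motif[pos]]
        if not choices:
            raise ValueError("alphabet too small to build a decoy")
        decoy = motif[:pos] + str(rng.choice(choices)) + motif[pos + 1 :]

    def plant(payload: str, forbid: str) -> tuple[str, int]:
        from .motifs import locate_motif

        for _ in range(_REJECTION_BUDGET):
            seq = _random_seq(rng, spec.length - len(payload), spec.alphabet)
            start = int(rng.integers(len(seq) + 1))
            full = seq[:start] + payload + seq[start:]
            if len(locate_motif(full, payload)) != 1:
                continue
            if payload != forbid and forbid in full:
                continue
            return full, start + 1
        raise ValueError(
            f"rejection budget exhausted planting {payload!r}; "
            "motif too short for this alphabet/length"
        )

    def background(forbid: str) -> str:
        for _ in range(_REJECTION_BUDGET):
            seq = _random_seq(rng, spec.length, spec.alphabet)
            if forbid not in seq:
                return seq
        raise ValueError(
            f"rejection budget exhausted excluding {forbid!r} from negatives; "
            "motif too short for this alphabet/length"
        )

    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    positions: dict[str, int] = {}
    for i in range(spec.n_positives):
        seq, pos1 = plant(motif, motif)
        rid = f"pos{i + 1}"
        records.append(ProteinRecord(id=rid, sequence=seq))
        labels[rid] = "binder"
        positions[rid] = pos1
    decoy_ids: list[str] = []
    for i in range(spec.n_negatives):
        rid = f"neg{i + 1}"
        if i < spec.n_decoy_negatives:
            seq, _ = plant(decoy, motif)
            decoy_ids.append(rid)
        else:
            seq = background(motif)
        records.append(ProteinRecord(id=rid, sequence=seq))
        labels[rid] = "nonbinder"
    sset = LabeledSequenceSet(records=tuple(records), labels=labels)
    truth = {
        "motif": motif,
        "positions": positions,
        "decoy": decoy,
        "decoy_ids": decoy_ids,
        "seed": spec.seed,
    }
    return sset, truth


def mutate_sequence(
    seq: str,
    n_substitutions: int,
    rng: np.random.Generator,
    alphabet: str = AA20,
    protected: tuple[int, int] | None = None,
) -> str:
    """Substitute exactly *n_substitutions* positions, each to a different
    residue.  ``protected`` is an optional half-open 0-based range never
    touched (used to preserve a planted motif)."""
    candidates = [
        i
        for i in range(len(seq))
        if protected is None or not (protected[0] <= i < protected[1])
    ]
    if n_substitutions > len(candidates):
        raise ValueError("not enough mutable positions")
    sites = rng.choice(len(candidates), size=n_substitutions, replace=False)
    out = list(seq)
    for s in sites:
        i = candidates[int(s)]
        choices = [c for c in alphabet if c != out[i]]
        out[i] = str(rng.choice(choices))
    return "".join(out)


def simulate_ortholog_pair(
    identity: float,
    length: int,
    seed: int = 0,
    id_prefix: str = "orth",
    alphabet: str = AA20,
) -> tuple[ProteinRecord, ProteinRecord, float]:
    """A substitution-only ortholog pair at a controlled percent identity.

    The second sequence differs from the first at exactly
    ``round(length * (1 - identity/100))`` positions (no indels); the
    recorded true identity is the exact substituted fraction.
    """
    if not 0 <= identity <= 100:
        raise ValueError("identity must be in [0, 100]")
    rng = np.random.default_rng(seed)
    a = _random_seq(rng, length, alphabet)
    n_sub = round(length * (1 - identity / 100))
    b = mutate_sequence(a, n_sub, rng, alphabet)
    true_identity = 100.0 * (length - n_sub) / length
    return (
        ProteinRecord(id=f"{id_prefix}_a", sequence=a),
        ProteinRecord(id=f"{id_prefix}_b", sequence=b),
        true_identity,
    )


def simulate_additive_matrix(
    n_taxa: int, seed: int = 0
) -> tuple[TreeNode, DistanceMatrix]:
    """A random unrooted binary tree and its exact path-length matrix.

    Built by sequential leaf attachment to a random edge; branch lengths
    drawn uniformly from (0.5, 5).  The matrix is additive by construction
    and therefore satisfies the four-point condition.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)

    def blen() -> float:
        return float(rng.uniform(0.5, 5.0))

    labels = [f"T{i + 1}" for i in range(n_taxa)]
    root = TreeNode()
    for lab in labels[:3]:
        leaf = TreeNode(name=lab, length=blen())
        root.append(leaf)
    for lab in labels[3:]:
        # pick a random existing edge (any non-root node) and split it
        edges = [n for n in root.traverse(include_self=False)]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = TreeNode(length=blen())
        old_len = target.length
        split = rng.uniform(0.2, 0.8)
        parent.remove(target)
        target.length = old_len * split
        mid.length = old_len * (1 - split)
        mid.append(target)
        mid.append(TreeNode(name=lab, length=blen()))
        parent.append(mid)
    dm = root.tip_tip_distances()
    order = [list(dm.ids).index(lab) for lab in labels]
    vals = dm.data[np.ix_(order, order)]
    return root, DistanceMatrix(labels=tuple(labels), values=vals)


def simulate_coip_lanes(
    true_binding: dict[str, float],
    reference_bait: str,
    bait_expression: dict[str, float] | None = None,
    background: float = 200.0,
    noise_sd: float = 0.0,
    bit_depth: int = 8,
    seed: int = 0,
    prey_input_signal: float = 120.0,
    capture_fraction: float = 0.8,
) -> tuple[list[CoIPLane], dict]:
    """Co-IP band panel from known bait-occupancy fractions.

    ``true_binding`` maps bait ids to the fraction of captured bait
    occupied by prey (in [0, 1]); band raw means are background - signal +
    Gaussian noise, clipped to the bit range (with a warning when clipping
    occurs).  With zero noise, downstream relative binding inverts exactly
    to ``true_binding[bait] / true_binding[reference]``.
    """
    import logging

    logger = logging.getLogger("palmkit")
    if reference_bait not in true_binding:
        raise ValueError("reference bait missing from true_binding")
    for bait, f in true_binding.items():
        if not 0 <= f <= 1:
            raise ValueError(f"binding fraction for {bait!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    top = 2**bit_depth - 1
    expr = bait_expression or {}
    lanes: list[CoIPLane] = []
    bands: dict = {}

    def raw(signal: float) -> float:
        value = background - signal + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        if not 0 <= value <= top:
            logger.warning("band raw mean %.2f clipped to [0, %d]", value, top)
        return float(np.clip(value, 0, top))

    for i, (bait, frac) in enumerate(true_binding.items(), start=1):
        level = expr.get(bait, 100.0)
        signals = {
            "prey_input": prey_input_signal,
            "bait_input": level,
            "bait_pd": level * capture_fraction,
            "prey_pd": frac * level * capture_fraction,
        }
        nets = {}
        for role, sig in signals.items():
            band = BandMeasurement(
                raw_mean=raw(sig), background_mean=background, bit_depth=bit_depth
            )
            bands[(f"lane{i}", bait, 1, role)] = band
            nets[role] = net_band_intensity(band)
        lanes.append(
            CoIPLane(lane_id=f"lane{i}", bait_id=bait, replicate=1, **nets)
        )
    ref_frac = true_binding[reference_bait]
    truth = {
        "true_binding": dict(true_binding),
        "true_relative": {
            b: (f / ref_frac if ref_frac > 0 else None)
            for b, f in true_binding.items()
        },
        "reference_bait": reference_bait,
        "seed": seed,
        "bands": bands,
    }
    return lanes, truth


@dataclass(frozen=True)
class DeathModelSpec:
    """Minimal growth/death model behind simulated count streams.

    Live cells grow exponentially at rate ``r`` until death onset
    ``t_on``, after which growth halts and cells die with constant hazard
    ``lam``; a dead cell stays double positive (SG+/mKate2+) for a dwell
    time ``tau`` before losing the live marker.  Frames every
    ``frame_interval`` hours out to ``horizon``.  The model's only job is
    to produce count streams with a known closed-form lethal fraction
    dead/(live + dead).
    """

    n0: float = 500.0
    r: float = 0.02
    t_on: float = 24.0
    lam: float = 0.08
    tau: float = 4.0
    frame_interval: float = 4.0
    horizon: float = 96.0
    noise: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("n0", "r", "lam", "tau"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.horizon <= self.t_on:
            raise ValueError("horizon must exceed death onset")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


def _expected_counts(spec: DeathModelSpec, t: float) -> tuple[float, float, float]:
    """(live, cumulative dead, recently dead within tau) at time t."""
    if t < spec.t_on:
        live = spec.n0 * math.exp(spec.r * t)
        return live, 0.0, 0.0
    peak = spec.n0 * math.exp(spec.r * spec.t_on)
    live = peak * math.exp(-spec.lam * (t - spec.t_on))
    dead = peak - live

    def dead_at(u: float) -> float:
        if u < spec.t_on:
            return 0.0
        return peak - peak * math.exp(-spec.lam * (u - spec.t_on))

    recent = dead - dead_at(t - spec.tau)
    return live, dead, recent


def simulate_death_timecourse(
    spec: DeathModelSpec,
) -> tuple[DeathTimecourse, np.ndarray]:
    """Count stream and analytic lethal-fraction series for the model.

    Noise-free counts are the real-valued model expectations; Poisson
    noise samples live cells, recently dead and older dead independently
    and assembles SG+ = recent + older and mKate2+ = live + recent, so the
    count ordering invariants (double+ <= SG+, double+ <= mKate2+) hold by
    construction.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.horizon + 1e-9, spec.frame_interval)
    tps = []
    analytic = []
    for t in times:
        live, dead, recent = _expected_counts(spec, float(t))
        analytic.append(dead / (live + dead) if live + dead > 0 else np.nan)
        if spec.noise == "poisson":
            live_s = float(rng.poisson(live))
            recent_s = float(rng.poisson(recent))
            older_s = float(rng.poisson(max(dead - recent, 0.0)))
            mkate2, sg, double = live_s + recent_s, recent_s + older_s, recent_s
        else:
            mkate2, sg, double = live + recent, dead, recent
        tps.append(
            DeathTimepoint(t=float(t), mkate2_pos=mkate2, sg_pos=sg, double_pos=double)
        )
    return DeathTimecourse(timepoints=tuple(tps), mode="dual"), np.array(analytic)
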