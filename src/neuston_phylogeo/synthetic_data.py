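"""Clade-structured haplotype sample simulator.

Generates FASTA + group-map datasets with the structure the analysis
stages assume: several divergent clades of closely related, AT-rich
mitochondrial-like haplotypes, with a tunable habitat-linked deficit of
the photolesion-promoting words TTA/TTT in neustonic sequences.

The genealogy within each clade is a star: a clade ancestor is drawn (or
derived from a common root by Poisson-many substitutions), and each tip
receives an independent Poisson(within_clade_lambda) number of
substitutions at distinct sites.  Mutations per lineage hit distinct
sites, so each tip's Hamming distance to its ancestor equals its Poisson
draw exactly; different tips may still collide at a site, which is what
the ground-truth record lets tests correct for.  Under this model the
expected mean pairwise difference within a clade is 2*lambda minus the
collision correction.

The TTA/TTT deficit is imposed post hoc: neustonic sequences are scanned
on the plus strand and each promoter word is independently destroyed with
probability (1 - tt_suppression) by replacing its third base with C or G.
The minus-strand deficit follows automatically because the complementary
words are depleted together.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io_formats import GroupMap, NucleotideSequence, SequenceSet

BASES = "ACGT"

#: AT-rich defaults in the spirit of an arthropod mitochondrial rRNA region.
DEFAULT_BASE_FREQS = (0.35, 0.15, 0.20, 0.30)  # A, C, G, T


@dataclass
class SimulationConfig:
    n_clades: int = 3
    seqs_per_clade: int = 20
    seq_length: int = 1100
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    within_clade_lambda: float = 5.0
    between_clade_divergence: float = 40.0
    habitat_assignment: dict[str, str] | None = None  # clade label -> habitat
    tt_suppression: float = 1.0  # 1 = no suppression
    seed: int = 0

    def __post_init__(self):
        if self.seq_length < 10:
            raise ConfigError("seq_length must be >= 10")
        if self.n_clades < 1 or self.seqs_per_clade < 2:
            raise ConfigError("need >= 1 clade and >= 2 sequences per clade")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ConfigError("base_freqs must sum to 1")
        if not 0.0 <= self.tt_suppression <= 1.0:
            raise ConfigError("tt_suppression must lie in [0, 1]")

    def clade_labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_clades)]

    def habitats(self) -> dict[str, str]:
        if self.habitat_assignment is not None:
            return dict(self.habitat_assignment)
        # default: alternate, first clade neustonic
        labels = self.clade_labels()
        return {
            lab: ("neustonic" if i % 2 == 0 else "planktonic")
            for i, lab in enumerate(labels)
        }


@dataclass
class GroundTruth:
    """Everything needed to re-derive the emitted sequences and to serve as
    an oracle for parameter-recovery tests."""

    seed: int
    clade_ancestors: dict[str, str]
    #: clade -> {tip id -> list of (site, original, new)} before suppression
    mutations: dict[str, dict[str, list[tuple[int, str, str]]]]
    #: habitat -> realized plus-strand TTA/TTT and TTC/TTG counts
    motif_density_before: dict[str, dict[str, int]] = field(default_factory=dict)
    motif_density_after: dict[str, dict[str, int]] = field(default_factory=dict)

    def expected_pairwise_difference(self, clade: str) -> float:
        """Within-clade mean pairwise difference implied by the realized
        mutations, counted directly from the mutation lists (collisions
        between lineages resolved site by site)."""
        tips = list(self.mutations[clade])
        total, pairs = 0, 0
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                a = {s: new for s, _, new in self.mutations[clade][tips[i]]}
                b = {s: new for s, _, new in self.mutations[clade][tips[j]]}
                diff = 0
                for site in set(a) | set(b):
                    ancestral = self.clade_ancestors[clade][site]
                    x = a.get(site, ancestral)
                    y = b.get(site, ancestral)
                    if x != y:
                        diff += 1
                total += diff
                pairs += 1
        return total / pairs if pairs else 0.0

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _random_sequence(rng: np.random.Generator, length: int, freqs) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=list(freqs)))


def _mutate(
    seq: str,
    n_mut: int,
    rng: np.random.Generator,
    freqs,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Apply ``n_mut`` substitutions at distinct uniformly chosen sites; the
    new state is drawn from ``freqs`` renormalized without the current one."""
    L = len(seq)
    while n_mut > L:
        warnings.warn(f"mutation count {n_mut} exceeds length {L}; resampled")
        n_mut = int(rng.poisson(L / 2))
    sites = rng.choice(L, size=n_mut, replace=False)
    chars = list(seq)
    events = []
    for site in sites:
        site = int(site)
        old = chars[site]
        others = [b for b in BASES if b != old]
        w = np.array([freqs[BASES.index(b)] for b in others], dtype=float)
        w = w / w.sum()
        new = str(rng.choice(others, p=w))
        chars[site] = new
        events.append((site, old, new))
    return "".join(chars), events


def suppress_tt_words(
    seq: str,
    factor: float,
    base_freqs=DEFAULT_BASE_FREQS,
    rng: np.random.Generator | None = None,
    max_passes: int = 20,
) -> str:
    """Destroy plus-strand TTA/TTT words, each with probability (1 - factor).

    Destruction replaces one of the word's bases by C or G (weighted by
    ``base_freqs``); substitutions only ever remove T's, so new promoter
    words are never created.  Because adjacent words share bases, the
    mutated position is chosen to spare designated-surviving neighbours
    (third base by default, first base when the right-hand neighbours
    should survive); only a destroyed word wedged between two survivors
    takes an unavoidable collateral.  With factor = 0 every scanned word
    is destroyed; a rescan loop guarantees none survive.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError("factor must lie in [0, 1]")
    if factor == 1.0:
        return seq
    if rng is None:
        rng = np.random.default_rng()
    p_cg = np.array([base_freqs[1], base_freqs[2]], dtype=float)
    p_cg = p_cg / p_cg.sum()
    chars = list(seq)

    def is_word(i: int) -> bool:
        return (
            0 <= i <= len(chars) - 3
            and chars[i] == "T"
            and chars[i + 1] == "T"
            and chars[i + 2] in "AT"
        )

    for _ in range(max_passes):
        hits = [i for i in range(len(chars) - 2) if is_word(i)]
        if not hits:
            break
        survives = {i: rng.random() < factor for i in hits}
        changed = False
        for i in hits:
            if survives[i] or not is_word(i):  # already collaterally gone
                continue
            third_safe = not (survives.get(i + 1) and is_word(i + 1)) and not (
                survives.get(i + 2) and is_word(i + 2)
            )
            first_safe = not (survives.get(i - 2) and is_word(i - 2)) and not (
                survives.get(i - 1) and is_word(i - 1)
            )
            pos = i + 2 if third_safe or not first_safe else i
            chars[pos] = str(rng.choice(["C", "G"], p=p_cg))
            changed = True
        if factor > 0.0 or not changed:
            break  # single stochastic pass; rescan only for certain destruction
    return "".join(chars)


def _plus_strand_counts(seq: str) -> dict[str, int]:
    from .motif_uvr import count_overlapping

    return {m: count_overlapping(seq, m) for m in ("TTA", "TTT", "TTC", "TTG")}


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[SequenceSet, GroupMap, GroundTruth]:
    """Simulate one clade-structured dataset; deterministic for fixed seed."""
    rng = np.random.default_rng(config.seed)
    freqs = config.base_freqs
    habitats = config.habitats()
    root = _random_sequence(rng, config.seq_length, freqs)

    ancestors: dict[str, str] = {}
    mutations: dict[str, dict[str, list[tuple[int, str, str]]]] = {}
    sequences: list[NucleotideSequence] = []
    entries: dict[str, tuple[str, str]] = {}
    before: dict[str, dict[str, int]] = {}
    after: dict[str, dict[str, int]] = {}

    for clade in config.clade_labels():
        n_div = int(rng.poisson(config.between_clade_divergence))
        ancestor, _ = _mutate(root, n_div, rng, freqs)
        ancestors[clade] = ancestor
        mutations[clade] = {}
        for t in range(config.seqs_per_clade):
            tip_id = f"{clade}_{t + 1:03d}"
            n_mut = int(rng.poisson(config.within_clade_lambda))
            residues, events = _mutate(ancestor, n_mut, rng, freqs)
            mutations[clade][tip_id] = events
            habitat = habitats[clade]
            pre = _plus_strand_counts(residues)
            if habitat == "neustonic" and config.tt_suppression < 1.0:
                residues = suppress_tt_words(
                    residues, config.tt_suppression, freqs, rng
                )
            post = _plus_strand_counts(residues)
            for store, cnt in ((before, pre), (after, post)):
                acc = store.setdefault(habitat, {m: 0 for m in cnt})
                for m, c in cnt.items():
                    acc[m] += c
            sequences.append(NucleotideSequence(tip_id, residues))
            entries[tip_id] = (clade, habitat)

    seqs = SequenceSet(sequences, is_alignment=True)
    gm = GroupMap(entries)
    truth = GroundTruth(
        seed=config.seed,
        clade_ancestors=ancestors,
        mutations=mutations,
        motif_density_before=before,
        motif_density_after=after,
    )
    return seqs, gm, truth
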