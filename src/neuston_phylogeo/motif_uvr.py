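"""Both-strand overlapping trinucleotide motif counting.

UV-induced pyrimidine photolesions form preferentially at TT dinucleotides,
and the 3' neighbour modulates the rate: TTA and TTT promote lesion
formation while TTC and TTG inhibit it.  This module counts those four
words per sequence with full overlap (``TTTT`` holds two ``TTT`` words) on
the plus strand and on the reverse complement, sums the strands, and
aggregates the promoter (TTA+TTT) and inhibitor (TTC+TTG) totals by
habitat group for the neustonic-versus-planktonic contrast.

Windows containing N or any other ambiguity code never match a motif, so
ambiguous bases can only deflate, never inflate, a count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GapError
from .io_formats import GroupMap, NucleotideSequence, SequenceSet

SALIENT_MOTIFS = ("TTA", "TTT", "TTC", "TTG")
PROMOTERS = ("TTA", "TTT")
INHIBITORS = ("TTC", "TTG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifCountRecord:
    """Per-sequence both-strand counts of the four salient trinucleotides."""

    sequence_id: str
    counts: dict[str, int]
    effective_length: int

    @property
    def promoter_sum(self) -> int:
        return sum(self.counts[m] for m in PROMOTERS)

    @property
    def inhibitor_sum(self) -> int:
        return sum(self.counts[m] for m in INHIBITORS)


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed; N maps to N; gaps are rejected."""
    if "-" in seq:
        raise GapError("reverse_complement requires a dealigned sequence")
    unknown = set(seq) - set("ACGTN")
    if unknown:
        raise ValueError(f"cannot complement characters {sorted(unknown)}")
    return seq.translate(_COMPLEMENT)[::-1]


def count_overlapping(seq: str, motif: str) -> int:
    """Number of start positions where ``motif`` occurs, overlaps included.

    ``str.count`` skips overlapping matches, so the scan advances one
    position per hit instead.
    """
    if len(motif) != 3 or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be a 3-mer over ACGT, got {motif!r}")
    n = 0
    start = seq.find(motif)
    while start != -1:
        n += 1
        start = seq.find(motif, start + 1)
    return n


def count_salient(seq: NucleotideSequence | str) -> MotifCountRecord:
    """Both-strand counts of TTA/TTT/TTC/TTG for one dealigned sequence."""
    if isinstance(seq, NucleotideSequence):
        sid, residues = seq.id, seq.residues
    else:
        sid, residues = "<anonymous>", seq
    if "-" in residues:
        raise GapError(f"sequence {sid!r} contains gaps; dealign first")
    # Ambiguity codes other than N would fail the complement; mask them to N
    # so their windows simply never match.
    masked = "".join(c if c in "ACGTN" else "N" for c in residues)
    rc = reverse_complement(masked)
    counts = {
        m: count_overlapping(masked, m) + count_overlapping(rc, m)
        for m in SALIENT_MOTIFS
    }
    return MotifCountRecord(sid, counts, len(residues))


def count_all(seqs: SequenceSet) -> list[MotifCountRecord]:
    return [count_salient(s) for s in seqs]


def records_frame(records: list[MotifCountRecord]) -> pd.DataFrame:
    """Per-sequence count table with raw and per-kilobase columns."""
    rows = []
    for r in records:
        kb = r.effective_length / 1000 if r.effective_length else np.nan
        rows.append(
            {
                "id": r.sequence_id,
                **{m: r.counts[m] for m in SALIENT_MOTIFS},
                "promoter_sum": r.promoter_sum,
                "inhibitor_sum": r.inhibitor_sum,
                "effective_length": r.effective_length,
                "promoter_per_kb": r.promoter_sum / kb if kb else np.nan,
                "inhibitor_per_kb": r.inhibitor_sum / kb if kb else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_by_group(
    records: list[MotifCountRecord], groups: GroupMap
) -> pd.DataFrame:
    """Five-number summary of promoter/inhibitor sums per habitat.

    Quartiles use linear interpolation between order statistics (the
    default "type 7" rule of numpy and R).  Empty habitat groups are
    omitted with a warning.
    """
    rows = []
    for habitat in ("neustonic", "planktonic"):
        ids = set(groups.habitat_members(habitat))
        vals = [r for r in records if r.sequence_id in ids]
        if not vals:
            warnings.warn(f"no sequences in habitat group {habitat!r}; omitted")
            continue
        for cls, getter in (
            ("promoter", lambda r: r.promoter_sum),
            ("inhibitor", lambda r: r.inhibitor_sum),
        ):
            x = np.array([getter(r) for r in vals], dtype=float)
            rows.append(
                {
                    "habitat": habitat,
                    "motif_class": cls,
                    "n": len(x),
                    "min": float(x.min()),
                    "q1": float(np.quantile(x, 0.25)),
                    "median": float(np.median(x)),
                    "q3": float(np.quantile(x, 0.75)),
                    "max": float(x.max()),
                }
            )
    return pd.DataFrame(rows)


def boxplot_by_group(records, groups, path) -> None:
    """Habitat box plots of promoter and inhibitor sums (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=False)
    for ax, (cls, getter) in zip(
        axes,
        (
            ("promoter (TTA/TTT)", lambda r: r.promoter_sum),
            ("inhibitor (TTC/TTG)", lambda r: r.inhibitor_sum),
        ),
    ):
        data, labels, colors = [], [], []
        for habitat, color in (("neustonic", "#f2a9c4"), ("planktonic", "#9ec9e2")):
            ids = set(groups.habitat_members(habitat))
            vals = [getter(r) for r in records if r.sequence_id in ids]
            if vals:
                data.append(vals)
                labels.append(f"{habitat}\n(n={len(vals)})")
                colors.append(color)
        bp = ax.boxplot(data, tick_labels=labels, patch_artist=True)
        for patch, color in zip(bp["boxes"], colors):
            patch.set_facecolor(color)
        ax.set_title(cls)
        ax.set_ylabel("both-strand count")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
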