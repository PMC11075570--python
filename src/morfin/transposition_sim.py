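"""Tn5 transposition into a circular plasmid, with 9-bp target-site duplication.

Tn5 cuts the two target strands 9 nt apart, leaving complementary 9-nt
overhangs; after the transposase ligates the donor and the host fills the
gaps, the 9-nt target sequence flanks the insert as a direct repeat.  The
cut-bond convention used here: ``cut_bond`` is the bond at the LEFT edge of
the duplicated 9-mer, so when the cut falls on a codon boundary of an
annotated ORF, "codon N" (the codon immediately preceding the cut) ends at
plasmid base ``cut_bond - 1`` and codons N+1..N+3 form the overhang.

Insertion sites are modelled as uniform over the plasmid and donor
orientation as a fair coin — hotspot preferences are deliberately not
modelled, though ``simulate_library`` accepts a user-supplied position
weight vector.  Each event carries exactly one insertion (the 1:1
amplicon:target molar-ratio regime; multiply-inserted plasmids enter the
screening model only through the single-insertion frequency factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .amplicon_designer import DonorAmplicon
from .seq_core import ParameterError, PlasmidRecord, TopologyError, revcomp

__all__ = [
    "TSD_LEN",
    "InsertionEvent",
    "insert_at",
    "simulate_library",
    "write_events_tsv",
    "read_events_tsv",
]

#: Length of the target-site duplication produced by the staggered cut.
TSD_LEN = 9

ORIENTATIONS = ("forward", "reverse")


@dataclass
class InsertionEvent:
    """One transposition of a donor amplicon into a plasmid.

    ``orientation`` is the amplicon ORF strand relative to the plasmid's
    ``+`` strand.  The post-repair circular product is assembled lazily
    (see :attr:`product`) so large event lists stay cheap; its length is
    always ``len(plasmid) + len(amplicon) + 9``.
    """

    cut_bond: int
    orientation: str
    duplication: str
    plasmid: PlasmidRecord = field(repr=False)
    amplicon: DonorAmplicon = field(repr=False)
    event_id: int = 0

    @property
    def inserted_sequence(self) -> str:
        """The donor as it appears on the plasmid + strand."""
        seq = self.amplicon.sequence
        return seq if self.orientation == "forward" else revcomp(seq)

    @property
    def product_length(self) -> int:
        return len(self.plasmid) + len(self.amplicon) + TSD_LEN

    @property
    def insert_offset(self) -> int:
        """Offset of the inserted donor within :attr:`product`."""
        L = len(self.plasmid)
        return self.cut_bond + TSD_LEN if self.cut_bond + TSD_LEN <= L else TSD_LEN

    @property
    def product(self) -> str:
        """The repaired circular product, linearized.

        For cuts not reaching the origin the string starts at plasmid
        position 0: ``P[0:cut+9) + insert + P[cut:L)``.  For cuts whose
        9-mer wraps the origin the (circular) product is returned rotated
        to start at the first duplication copy.
        """
        P = self.plasmid.sequence
        L = len(P)
        cut = self.cut_bond
        if cut + TSD_LEN <= L:
            return P[: cut + TSD_LEN] + self.inserted_sequence + P[cut:]
        around = (P + P)[cut : cut + L]  # rotation starting at the cut
        return around[:TSD_LEN] + self.inserted_sequence + around

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ParameterError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )


def insert_at(
    plasmid: PlasmidRecord,
    amplicon: DonorAmplicon,
    cut_bond: int,
    orientation: str = "forward",
    event_id: int = 0,
) -> InsertionEvent:
    """Insert ``amplicon`` at ``cut_bond`` with the 9-bp duplication mechanics."""
    L = len(plasmid)
    if not 0 <= cut_bond < L:
        raise ParameterError(f"cut_bond {cut_bond} outside [0, {L})")
    if not plasmid.circular and cut_bond + TSD_LEN > L:
        raise TopologyError(
            f"cut at bond {cut_bond} reaches within {TSD_LEN} nt of the end of the "
            f"linear record {plasmid.name!r}"
        )
    duplication = plasmid.fetch(cut_bond, cut_bond + TSD_LEN)
    return InsertionEvent(
        cut_bond=cut_bond,
        orientation=orientation,
        duplication=duplication,
        plasmid=plasmid,
        amplicon=amplicon,
        event_id=event_id,
    )


def simulate_library(
    plasmid: PlasmidRecord,
    amplicon: DonorAmplicon,
    n_events: int,
    seed: int,
    position_weights: Sequence[float] | None = None,
) -> list[InsertionEvent]:
    """Draw ``n_events`` independent single-insertion events.

    Cut bonds are i.i.d. uniform over ``0..L-1`` (or proportional to
    ``position_weights`` of length L, if given) and orientation is a fair
    Bernoulli draw.  Identical seeds give identical event lists.
    """
    if n_events < 1:
        raise ParameterError(f"n_events must be >= 1, got {n_events}")
    L = len(plasmid)
    rng = np.random.default_rng(seed)
    if position_weights is None:
        cuts = rng.integers(0, L, size=n_events)
    else:
        w = np.asarray(position_weights, dtype=float)
        if w.shape != (L,) or (w < 0).any() or w.sum() <= 0:
            raise ParameterError(
                f"position_weights must be {L} non-negative values with positive sum"
            )
        cuts = rng.choice(L, size=n_events, p=w / w.sum())
    orients = rng.integers(0, 2, size=n_events)
    return [
        insert_at(
            plasmid,
            amplicon,
            int(cut),
            ORIENTATIONS[int(o)],
            event_id=i,
        )
        for i, (cut, o) in enumerate(zip(cuts, orients))
    ]


def write_events_tsv(events: Sequence[InsertionEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "cut_bond": [e.cut_bond for e in events],
            "orientation": [e.orientation for e in events],
            "duplication": [e.duplication for e in events],
            "product_length": [e.product_length for e in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(
    path: str | Path, plasmid: PlasmidRecord, amplicon: DonorAmplicon
) -> list[InsertionEvent]:
    """Rehydrate events against the plasmid/amplicon they were simulated on."""
    df = pd.read_csv(path, sep="\t")
    events = [
        insert_at(
            plasmid,
            amplicon,
            int(row.cut_bond),
            str(row.orientation),
            event_id=int(row.event_id),
        )
        for row in df.itertuples()
    ]
    for ev, dup in zip(events, df["duplication"]):
        if ev.duplication != dup:
            raise ParameterError(
                f"event {ev.event_id}: recorded duplication {dup!r} does not match "
                f"plasmid sequence at bond {ev.cut_bond} ({ev.duplication!r}); "
                "wrong plasmid for this event file?"
            )
    return events
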