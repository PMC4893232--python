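"""In-silico host identification from cytochrome-b amplicons.

Mirrors the wet-lab workflow computationally: degenerate PCR primers are
located in template sequences under IUPAC-aware matching, the flanked
fragment (primer footprints included) is extracted as the amplicon, and a
query amplicon is assigned to the host taxon whose reference it aligns to
with the highest identity. Identification is two-tier: queries that fail
against the first primer pair's reference panel are retried against the
second pair's panel, echoing the fallback PCR used when the primary primers
fail to amplify.

Published cytochrome-b primer pairs are provided as constants: L2513/H2714
(~244 bp product) and the fallback L14841/H15149 (~358 bp).

Scoring is fixed: global alignment with match +1, mismatch 0, linear gap
penalty -1; identity = identical columns / total aligned columns. For
equal-length ungapped sequences this reduces to 1 - Hamming/length. The
identity threshold (default 0.95) and ambiguity margin (default 0.02) are
explicit parameters, chosen to separate congeneric references in the
synthetic panels; real reference databases may warrant different values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes as base-set bitmasks (A=1, C=2, G=4, T=8)
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8, "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "U": 8,
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNU", "TGCAYRSWMKVHDBNA")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_IUPAC_BITS[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both primers written 5'->3' as synthesized
    (the reverse primer is the reverse complement of the top strand)."""

    name: str
    forward_sequence: str
    reverse_sequence: str
    expected_length: int

    def __post_init__(self) -> None:
        for seq in (self.forward_sequence, self.reverse_sequence):
            if not seq:
                raise ValueError("primer sequences must be non-empty")
            _encode(seq)  # validates the alphabet


#: cytochrome-b primer pairs used for host typing
KITANO_PAIR = PrimerPair(
    name="L2513/H2714",
    forward_sequence="GCCTGTTTACCAAAAACATCAC",
    reverse_sequence="CTCCATAGGGTCTTCTCGTCTT",
    expected_length=244,
)
KOCHER_PAIR = PrimerPair(
    name="L14841/H15149",
    forward_sequence="CCATCCAACATCTCAGCATGATGAAA",
    reverse_sequence="CCCTCAGAATGATATTTGTCCTCA",
    expected_length=358,
)


@dataclass(frozen=True)
class ReferencePanel:
    """Reference sequences keyed by host taxon name (uppercase-normalized)."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("taxon names in a panel must be unique")
        if any(not s for _, s in self.entries):
            raise ValueError("panel sequences must be non-empty")
        object.__setattr__(
            self, "entries", tuple((n, s.upper()) for n, s in self.entries)
        )

    def __len__(self) -> int:
        return len(self.entries)

    def taxa(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferencePanel":
        # full header line as the taxon name: binomials contain spaces
        return cls(
            tuple((rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))
        )

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, seq in self.entries:
                fh.write(f">{name}\n{seq}\n")


@dataclass(frozen=True)
class HostCall:
    query_id: str
    best_taxon: str | None
    identity: float
    margin: float
    status: str  # assigned | ambiguous | unassigned
    tier: str | None = None

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "taxon": self.best_taxon,
            "identity": self.identity,
            "margin": self.margin,
            "status": self.status,
            "tier": self.tier,
        }


def find_primer_site(
    template: str, primer: str, max_mismatches: int = 2
) -> list[tuple[int, str, int]]:
    """All primer binding sites in a template under IUPAC-aware matching.

    Scans the primer on the plus strand and its reverse complement on the
    plus strand (reported as minus-strand hits). A primer code matches any
    base in its degeneracy set; N matches everything. Returns 0-based
    half-open start positions with strand and mismatch count. A primer
    longer than the template yields an empty list.
    """
    if not template:
        raise ValueError("template must be non-empty")
    t = _encode(template)
    hits: list[tuple[int, str, int]] = []
    for strand, pseq in (("+", primer), ("-", reverse_complement(primer))):
        p = _encode(pseq)
        if p.size > t.size:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(t, p.size)
        mismatches = np.count_nonzero((windows & p) == 0, axis=1)
        for pos in np.flatnonzero(mismatches <= max_mismatches):
            hits.append((int(pos), strand, int(mismatches[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def extract_amplicon(
    template: str, pair: PrimerPair, max_mismatches: int = 2
) -> str | None:
    """The PCR product of a primer pair on a template, or None.

    The forward primer must match the plus strand and the reverse primer's
    reverse complement must occur downstream in the correct orientation; the
    product spans primer footprint to primer footprint inclusive. If several
    products are possible, the shortest is returned (shorter products
    dominate PCR). Absence of either site is a None result, not an error.
    """
    fwd = [h for h in find_primer_site(template, pair.forward_sequence, max_mismatches) if h[1] == "+"]
    # reverse primer as synthesized anneals to the plus strand read 3'->5';
    # its reverse complement appears verbatim on the plus strand
    rev = [h for h in find_primer_site(template, pair.reverse_sequence, max_mismatches) if h[1] == "-"]
    rev_len = len(pair.reverse_sequence)
    best: str | None = None
    for fpos, _, _ in fwd:
        for rpos, _, _ in rev:
            end = rpos + rev_len
            if rpos >= fpos + len(pair.forward_sequence):
                product = template[fpos:end]
                if best is None or len(product) < len(best):
                    best = product
    return best


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def _identity(aligner: Align.PairwiseAligner, query: str, reference: str) -> float:
    alignment = aligner.align(query.upper(), reference.upper())[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def assign_host(
    query: str,
    panel: ReferencePanel,
    min_identity: float = 0.95,
    min_margin: float = 0.02,
    query_id: str = "query",
) -> HostCall:
    """Best-identity host assignment of a query amplicon against a panel.

    assigned: best identity >= min_identity and the gap to the second-best
    taxon >= min_margin; ambiguous: identity reached but the margin did not
    (including exact ties); unassigned: no reference reached the threshold.
    """
    if not query:
        raise ValueError("query sequence must be non-empty")
    if len(panel) == 0:
        raise ValueError("reference panel must be non-empty")
    aligner = _make_aligner()
    scored = sorted(
        ((_identity(aligner, query, seq), name) for name, seq in panel.entries),
        key=lambda t: (-t[0], t[1]),
    )
    best_id, best_taxon = scored[0]
    margin = best_id - scored[1][0] if len(scored) > 1 else best_id
    if best_id < min_identity:
        return HostCall(query_id, None, best_id, margin, "unassigned")
    if margin < min_margin:
        return HostCall(query_id, best_taxon, best_id, margin, "ambiguous")
    return HostCall(query_id, best_taxon, best_id, margin, "assigned")


def two_tier_identify(
    queries: list[tuple[str, str]],
    tier_panels: list[tuple[str, ReferencePanel]],
    min_identity: float = 0.95,
    min_margin: float = 0.02,
) -> list[HostCall]:
    """Tiered identification: each query is matched against the first panel;
    only *unassigned* queries fall through to the next tier. The tier that
    produced each call is recorded; order and count of queries are preserved.
    """
    if not tier_panels:
        raise ValueError("at least one tier panel is required")
    calls: list[HostCall] = []
    for query_id, seq in queries:
        call: HostCall | None = None
        for tier_name, panel in tier_panels:
            attempt = assign_host(seq, panel, min_identity, min_margin, query_id)
            call = HostCall(
                query_id=attempt.query_id,
                best_taxon=attempt.best_taxon,
                identity=attempt.identity,
                margin=attempt.margin,
                status=attempt.status,
                tier=tier_name,
            )
            if call.status != "unassigned":
                break
        calls.append(call)
    return calls


def write_calls(calls: list[HostCall], path: str | Path, sep: str = ",") -> None:
    import pandas as pd

    pd.DataFrame([c.to_dict() for c in calls]).to_csv(path, index=False, sep=sep)


def read_fasta_queries(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
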