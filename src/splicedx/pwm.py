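"""Position-weight-matrix scoring of donor and acceptor splice sites.

The scorer is a plain log-odds PWM over a fixed window:

* donor:    9 nt spanning the last 3 exonic bases and the first 6 intronic
  bases (``...CAG | GTAAGT...``),
* acceptor: 23 nt spanning the last 20 intronic bases (polypyrimidine tract
  plus the invariant AG) and the first 3 exonic bases.

The bundled base frequencies follow the classic human U2-type consensus
(Shapiro & Senapathy-style column frequencies, lightly smoothed so no
column carries a zero). They are versioned in-source data: the matrices are
part of the package's contract, and the synthetic-data generator writes the
consensus of these same matrices at every canonical junction it emits, so
native sites in simulated panels score at the PWM maximum by construction.

Scores are sums over columns of ``log2(f_base / 0.25)``; an ``N`` base
contributes exactly 0 (its probability is the column mean, which is the
background). Higher is stronger; the consensus sequence attains
:func:`max_score`.
"""

from __future__ import annotations

import math
from typing import Dict, List

DONOR_WINDOW = 9  #: 3 exonic + 6 intronic bases
ACCEPTOR_WINDOW = 23  #: 20 intronic + 3 exonic bases

#: Number of exonic bases at the start of a donor window.
DONOR_EXONIC = 3
#: Number of intronic bases at the start of an acceptor window.
ACCEPTOR_INTRONIC = 20

_BG = 0.25

# Column order for the donor: exonic -3..-1, intronic +1..+6.
DONOR_FREQS: List[Dict[str, float]] = [
    {"A": 0.33, "C": 0.37, "G": 0.18, "T": 0.12},  # -3
    {"A": 0.60, "C": 0.13, "G": 0.14, "T": 0.13},  # -2
    {"A": 0.08, "C": 0.04, "G": 0.81, "T": 0.07},  # -1
    {"A": 0.002, "C": 0.002, "G": 0.995, "T": 0.001},  # +1 (invariant G)
    {"A": 0.002, "C": 0.002, "G": 0.001, "T": 0.995},  # +2 (invariant T)
    {"A": 0.60, "C": 0.03, "G": 0.34, "T": 0.03},  # +3
    {"A": 0.70, "C": 0.08, "G": 0.12, "T": 0.10},  # +4
    {"A": 0.06, "C": 0.06, "G": 0.84, "T": 0.04},  # +5
    {"A": 0.16, "C": 0.12, "G": 0.22, "T": 0.50},  # +6
]

# Column order for the acceptor: intronic -20..-1, exonic +1..+3.
_PPT = {"A": 0.10, "C": 0.31, "G": 0.10, "T": 0.49}  # polypyrimidine tract
ACCEPTOR_FREQS: List[Dict[str, float]] = (
    [dict(_PPT) for _ in range(16)]  # -20..-5
    + [
        {"A": 0.20, "C": 0.35, "G": 0.15, "T": 0.30},  # -4
        {"A": 0.05, "C": 0.65, "G": 0.05, "T": 0.25},  # -3
        {"A": 0.994, "C": 0.002, "G": 0.002, "T": 0.002},  # -2 (invariant A)
        {"A": 0.002, "C": 0.002, "G": 0.994, "T": 0.002},  # -1 (invariant G)
        {"A": 0.24, "C": 0.15, "G": 0.50, "T": 0.11},  # +1
        {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},  # +2
        {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},  # +3
    ]
)

_MATRICES = {"donor": DONOR_FREQS, "acceptor": ACCEPTOR_FREQS}
_WINDOWS = {"donor": DONOR_WINDOW, "acceptor": ACCEPTOR_WINDOW}


def window_length(site_type: str) -> int:
    """Length of the PWM window for ``site_type`` ('donor' or 'acceptor')."""
    try:
        return _WINDOWS[site_type]
    except KeyError:
        raise ValueError(f"unknown site type: {site_type!r}") from None


def splice_site_strength(seq: str, site_type: str) -> float:
    """Log-odds PWM score of a splice-site window.

    Parameters
    ----------
    seq:
        Nucleotide window in transcript orientation; 9 nt for a donor
        (exonic -3..-1 plus intronic +1..+6), 23 nt for an acceptor
        (intronic -20..-1 plus exonic +1..+3).
    site_type:
        ``'donor'`` or ``'acceptor'``.

    Returns
    -------
    float
        Sum over columns of ``log2(f / 0.25)``. ``N`` contributes 0.

    Raises
    ------
    ValueError
        If the window length does not match the PWM, or the sequence
        contains a symbol other than A/C/G/T/N.
    """
    matrix = _MATRICES.get(site_type)
    if matrix is None:
        raise ValueError(f"unknown site type: {site_type!r}")
    seq = seq.upper()
    if len(seq) != len(matrix):
        raise ValueError(
            f"{site_type} window must be {len(matrix)} nt, got {len(seq)} nt"
        )
    score = 0.0
    for base, col in zip(seq, matrix):
        if base == "N":
            continue  # column mean equals background: contributes 0
        try:
            score += math.log2(col[base] / _BG)
        except KeyError:
            raise ValueError(f"invalid nucleotide {base!r} in window") from None
    return score


def max_score(site_type: str) -> float:
    """The score attained by the consensus window."""
    matrix = _MATRICES.get(site_type)
    if matrix is None:
        raise ValueError(f"unknown site type: {site_type!r}")
    return sum(math.log2(max(col.values()) / _BG) for col in matrix)


def consensus(site_type: str) -> str:
    """Consensus sequence of the PWM (ties broken in A<C<G<T order)."""
    matrix = _MATRICES.get(site_type)
    if matrix is None:
        raise ValueError(f"unknown site type: {site_type!r}")
    return "".join(max(sorted(col), key=lambda b: col[b]) for col in matrix)
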