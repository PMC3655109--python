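"""IUPAC nucleotide codes and edit-distance matching for primers and barcodes.

Degenerate PCR primers are written with IUPAC ambiguity codes (e.g. ``D`` =
A/G/T); matching them against reads must treat any base in the code's set as
an exact match while still charging unit cost for substitutions and indels.
Alignment is delegated to edlib with an equality list derived from the code
table.
"""

from __future__ import annotations

from functools import lru_cache

import edlib

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_nucleotides(s: str, *, iupac_ok: bool) -> None:
    allowed = IUPAC.keys() if iupac_ok else "ACGT"
    bad = set(s) - set(allowed)
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)!r} in {s[:30]!r}")


@lru_cache(maxsize=None)
def _equalities(pattern_chars: frozenset[str]) -> tuple[tuple[str, str], ...]:
    pairs = []
    for code in pattern_chars:
        for base in IUPAC[code]:
            if base != code:
                pairs.append((code, base))
    return tuple(pairs)


def match_iupac(
    pattern: str, sequence: str, max_edits: int = 1
) -> tuple[int, tuple[int, int]] | None:
    """Best IUPAC-aware match of ``pattern`` anywhere inside ``sequence``.

    A pattern position matches a sequence base when the base belongs to the
    IUPAC set of the pattern code; mismatches, insertions and deletions cost 1.
    Returns ``(distance, (start, end))`` with a half-open span into
    ``sequence``, or ``None`` when no alignment with distance <= ``max_edits``
    exists.
    """
    if not pattern:
        raise ValueError("empty pattern")
    if max_edits < 0:
        raise ValueError("max_edits must be >= 0")
    _check_nucleotides(pattern, iupac_ok=True)
    _check_nucleotides(sequence, iupac_ok=True)
    res = edlib.align(
        pattern,
        sequence,
        mode="HW",
        task="locations",
        k=max_edits,
        additionalEqualities=list(_equalities(frozenset(pattern))),
    )
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], (start, end + 1)


def edit_distance(a: str, b: str) -> int:
    """Global (Levenshtein) edit distance between two nucleotide strings."""
    return edlib.align(a, b, mode="NW")["editDistance"]


def prefix_distance(query: str, target: str) -> int:
    """Edit distance of ``query`` against the best-matching prefix of ``target``."""
    if not target:
        return len(query)
    return edlib.align(query, target, mode="SHW")["editDistance"]


def suffix_distance(query: str, target: str) -> int:
    """Edit distance of ``query`` against the best-matching suffix of ``target``."""
    if not target:
        return len(query)
    return edlib.align(query[::-1], target[::-1], mode="SHW")["editDistance"]


def realize(pattern: str, rng) -> str:
    """Replace degenerate positions with a uniformly sampled allowed base."""
    out = []
    for code in pattern:
        bases = sorted(IUPAC[code])
        out.append(bases[0] if len(bases) == 1 else bases[rng.integers(len(bases))])
    return "".join(out)
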