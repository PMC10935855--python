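"""Independent oracles used by the test suite.

These deliberately avoid the package's scanning/counting code paths: naive
every-window matching, find()-based occurrence counting, and brute-force set
accounting, so agreement with the implementation is evidence, not tautology.
"""

from __future__ import annotations

from itertools import combinations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def _window_matches(window: str, pattern: str) -> bool:
    return all(b in IUPAC[p] for b, p in zip(window, pattern))


def naive_scan(seq: str, pattern: str, both_strands: bool = True):
    """Check every window on both strands; (offset, strand, matched) triples."""
    seq, pattern = seq.upper(), pattern.upper()
    L, k = len(seq), len(pattern)
    rc = naive_revcomp(pattern)
    hits = []
    for i in range(L - k + 1):
        window = seq[i : i + k]
        if _window_matches(window, pattern):
            hits.append((i - L, "+", window))
        if both_strands and rc != pattern and _window_matches(window, rc):
            hits.append((i - L, "-", window))
    hits.sort(key=lambda t: (t[0], t[1]))
    return hits


def find_offsets(seq: str, word: str) -> list[int]:
    """All occurrences of a plain word via str.find (both-strand caller folds)."""
    seq, word = seq.upper(), word.upper()
    L = len(seq)
    out, i = [], seq.find(word)
    while i != -1:
        out.append(i - L)
        i = seq.find(word, i + 1)
    return out


def both_strand_offsets(seq: str, word: str) -> list[int]:
    rc = naive_revcomp(word)
    offs = find_offsets(seq, word)
    if rc != word:
        offs = sorted(set(offs) | set(find_offsets(seq, rc)))
    return offs


def max_nonoverlapping(offsets: list[int], k: int) -> int:
    """Exhaustive maximum non-overlapping selection (small inputs only)."""
    offsets = sorted(set(offsets))
    n = len(offsets)
    best = 0
    for r in range(n, 0, -1):
        for combo in combinations(offsets, r):
            if all(b - a >= k for a, b in zip(combo, combo[1:])):
                return r
    return best


def brute_force_regions(sets: dict[str, set]):
    """Exclusive-region counts from a gene-by-set membership table."""
    regions: dict[frozenset, int] = {}
    for gene in set().union(*sets.values()):
        sig = frozenset(name for name, members in sets.items() if gene in members)
        regions[sig] = regions.get(sig, 0) + 1
    return regions


def brute_force_conserved(group, word: str, presence_threshold=0.75,
                          position_window=200, min_orthologs=8):
    """Re-derive the conservation verdict with find()-based matching.

    Same rule as the package's classifier, reached through an independent
    matching path: any-hit agreement within the window of the focal hit
    nearest the start codon.
    """
    offsets = {sp: both_strand_offsets(rec.sequence, word)
               for sp, rec in group.promoters.items()}
    focal = offsets[group.focal_species]
    n = len(offsets)
    if not focal or n < min_orthologs:
        return False
    ref = max(focal)
    n_win = sum(1 for v in offsets.values()
                if any(abs(o - ref) <= position_window for o in v))
    return n_win / n >= presence_threshold
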