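"""Character-level edit distance used to constrain and audit correction candidates.

The distance implemented here is the *optimal string alignment* (OSA) form of
the Damerau-Levenshtein distance: the minimum number of single-character
insertions, deletions, substitutions, and adjacent transpositions needed to
turn one string into another, under the restriction that no substring is
edited more than once.  OSA is the variant used throughout spell-checking
systems (SymSpell and friends).  It is *not* a true metric — the triangle
inequality can fail (e.g. d("ca","abc") = 3 while d("ca","ab") + d("ab","abc")
= 2) — but it is symmetric, non-negative, and zero exactly on equal strings,
which is all candidate filtering needs.
"""

from __future__ import annotations

__all__ = ["damerau_levenshtein"]


def damerau_levenshtein(a: str, b: str) -> int:
    """Optimal-string-alignment Damerau-Levenshtein distance between two strings.

    Parameters
    ----------
    a, b:
        Input strings (may be empty).  Comparison is exact on code points;
        callers that want case-insensitive behaviour should pass normalized
        forms.

    Returns
    -------
    int
        Minimum number of insertions, deletions, substitutions, and adjacent
        transpositions converting ``a`` into ``b``, each substring edited at
        most once.

    Examples
    --------
    >>> damerau_levenshtein("stapylococcus", "staphylococcus")
    1
    >>> damerau_levenshtein("ab", "ba")
    1
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la

    # Classic three-row dynamic program: prev2/prev/cur are rows i-2, i-1, i
    # of the (la+1) x (lb+1) OSA matrix.
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ca == b[j - 1] else 1
            d = min(
                prev[j] + 1,        # deletion
                cur[j - 1] + 1,     # insertion
                prev[j - 1] + cost, # substitution / match
            )
            if i > 1 and j > 1 and ca == b[j - 2] and a[i - 2] == b[j - 1]:
                d = min(d, prev2[j - 2] + 1)  # adjacent transposition
            cur[j] = d
        prev2, prev = prev, cur
    return prev[lb]
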