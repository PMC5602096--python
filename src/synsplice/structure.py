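"""RNA secondary-structure providers and window features.

Single-nucleotide changes can remodel the local RNA secondary structure
around a putative binding site. Two features summarise this for a variant:
the average single-strandedness of the 15-nt window centred on the variant
(the variant plus 7 nt up- and downstream), and a distance between the
reference and alternative structures.

Providers are pluggable:

* :class:`NussinovProvider` — bundled, deterministic maximum base-pairing
  dynamic program (minimum loop length 3; GC/AU/GU pairs) emitting a
  dot-bracket string; the structure distance is the Levenshtein edit
  distance between dot-bracket strings. This is a deliberately simple,
  dependency-free approximation of a thermodynamic folder.
* :class:`ViennaRNAProvider` — minimum-free-energy folding through the
  ViennaRNA python bindings when they are importable, with base-pair
  distance between structures.

``get_provider("auto")`` prefers ViennaRNA and falls back to Nussinov.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .errors import MultipleDifferences, ProviderUnavailable

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


class NussinovProvider:
    """Maximum base-pairing folder (Nussinov DP) with dot-bracket output.

    Deterministic: ties in the DP are broken toward the unpaired branch,
    then toward the smallest pairing partner during traceback.
    """

    name = "nussinov"

    def __init__(self, min_loop: int = 3):
        self.min_loop = min_loop

    def fold(self, seq: str) -> str:
        rna = _to_rna(seq)
        n = len(rna)
        if n == 0:
            return ""
        h = self.min_loop
        can_pair = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + h + 1, n):
                if (rna[i], rna[j]) in _PAIRS:
                    can_pair[i, j] = True

        dp = np.zeros((n, n), dtype=np.int32)
        for span in range(h + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = dp[i, j - 1]  # j unpaired
                # j paired with some k in [i, j-h-1]
                ks = np.nonzero(can_pair[i : j - h, j])[0] + i
                for k in ks:
                    left = dp[i, k - 1] if k > i else 0
                    cand = left + dp[k + 1, j - 1] + 1
                    if cand > best:
                        best = cand
                dp[i, j] = best

        pairing = [-1] * n
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or j - i <= h:
                continue
            if dp[i, j] == dp[i, j - 1]:
                stack.append((i, j - 1))
                continue
            for k in range(i, j - h):
                if not can_pair[k, j]:
                    continue
                left = dp[i, k - 1] if k > i else 0
                if left + dp[k + 1, j - 1] + 1 == dp[i, j]:
                    pairing[k] = j
                    pairing[j] = k
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break

        db = []
        for i, p in enumerate(pairing):
            db.append("." if p < 0 else ("(" if p > i else ")"))
        return "".join(db)

    def distance(self, db_ref: str, db_alt: str) -> float:
        """Levenshtein edit distance between dot-bracket strings."""
        try:
            import edlib

            return float(edlib.align(db_ref, db_alt, task="distance")["editDistance"])
        except ImportError:  # pragma: no cover - edlib is a declared dep
            return float(_levenshtein(db_ref, db_alt))


def _levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class ViennaRNAProvider:
    """MFE folding via the ViennaRNA python bindings (when installed)."""

    name = "viennarna"

    def __init__(self):
        try:
            import RNA  # noqa: F401
        except ImportError as exc:
            raise ProviderUnavailable(
                "ViennaRNA python bindings are not importable"
            ) from exc
        self._rna = __import__("RNA")

    def fold(self, seq: str) -> str:
        db, _energy = self._rna.fold(_to_rna(seq))
        return db

    def distance(self, db_ref: str, db_alt: str) -> float:
        return float(self._rna.bp_distance(db_ref, db_alt))


def get_provider(name: str = "auto"):
    """Resolve a structure provider by name ('auto', 'nussinov', 'viennarna')."""
    if name == "nussinov":
        return NussinovProvider()
    if name == "viennarna":
        return ViennaRNAProvider()
    if name == "auto":
        try:
            return ViennaRNAProvider()
        except ProviderUnavailable:
            return NussinovProvider()
    raise ProviderUnavailable(f"unknown structure provider {name!r}")


def rna_structure_features(
    ref_context: str,
    alt_context: str,
    center: int,
    provider=None,
    flank: int = 7,
) -> tuple:
    """(average single-strandedness, structure distance) for one variant.

    ``ref_context``/``alt_context`` are the folding contexts (typically the
    variant +/- 50 nt of pre-mRNA) differing only at ``center`` (0-based);
    the single-strandedness is read off the central ``2*flank + 1`` positions
    of the folded reference structure; the distance compares the full ref
    and alt structures.
    """
    if len(ref_context) != len(alt_context):
        raise MultipleDifferences("ref and alt contexts differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(ref_context, alt_context)) if a != b]
    if len(diffs) > 1 or (diffs and diffs != [center]):
        raise MultipleDifferences(
            f"contexts differ at positions {diffs}, expected only {center}"
        )
    if provider is None:
        provider = get_provider("auto")
    db_ref = provider.fold(ref_context)
    db_alt = provider.fold(alt_context)
    lo = max(0, center - flank)
    hi = min(len(ref_context), center + flank + 1)
    window = db_ref[lo:hi]
    single_stranded = sum(1 for c in window if c == ".") / len(window)
    dist = provider.distance(db_ref, db_alt) if db_ref != db_alt else 0.0
    return float(single_stranded), float(dist)
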