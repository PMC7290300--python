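"""RNA secondary-structure folding behind a single pluggable contract.

A folding engine is anything with ``fold(seq) -> (dot_bracket, energy)``.
The default engine uses the ViennaRNA Python bindings (minimum free energy,
kcal/mol). A bundled fallback, :class:`MaxPairFolder`, is a plain
maximum-base-pairing dynamic program with simple stacking weights; it is
NOT thermodynamic and its "energy" is a pseudo-energy on an arbitrary
scale — it exists so the discovery pipeline can run and be tested without
an external folding library.
"""

from __future__ import annotations

from typing import Protocol

from ._seq import normalize


class FoldingError(RuntimeError):
    """The folding engine itself failed (distinct from a candidate rejection)."""


class FoldingEngine(Protocol):
    def fold(self, seq: str) -> tuple[str, float]: ...


class ViennaFolder:
    """Minimum-free-energy folding via the ViennaRNA `RNA` bindings."""

    def __init__(self) -> None:
        try:
            import RNA  # type: ignore
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise FoldingError("ViennaRNA python bindings (RNA) not importable") from exc
        self._rna = RNA

    def fold(self, seq: str) -> tuple[str, float]:
        s = normalize(seq).replace("T", "U")
        try:
            structure, dg = self._rna.fold(s)
        except Exception as exc:  # pragma: no cover - engine internal failure
            raise FoldingError(f"ViennaRNA fold failed: {exc}") from exc
        if len(structure) != len(s):
            raise FoldingError("engine returned structure of wrong length")
        return structure, float(dg)


# pair scores loosely reflecting stability order GC > AU > GU
_PAIR_SCORE = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}
_MIN_LOOP = 3


class MaxPairFolder:
    """Maximum base-pairing folder with a small stacking bonus.

    Non-thermodynamic fallback: a Nussinov-style O(n^3) dynamic program that
    maximises a pair score (GC=3, AU=2, GU=1, +0.5 per stacked pair) with a
    minimum hairpin loop of 3 nt. The returned "energy" is the negated score,
    so more paired structures are more negative, but the value is not in
    kcal/mol and must not be compared with true free energies.
    """

    stack_bonus = 0.5

    def fold(self, seq: str) -> tuple[str, float]:
        s = normalize(seq)
        n = len(s)
        if n == 0:
            return "", 0.0
        best = [[0.0] * n for _ in range(n)]
        choice = [[-1] * n for _ in range(n)]  # partner of i in window (i,j), -1 = unpaired i
        for span in range(_MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                # i unpaired
                b, c = best[i + 1][j], -1
                # i paired with k
                for k in range(i + _MIN_LOOP + 1, j + 1):
                    ps = _PAIR_SCORE.get((s[i], s[k]))
                    if ps is None:
                        continue
                    inner = best[i + 1][k - 1] if k - 1 > i + 1 else 0.0
                    right = best[k + 1][j] if k + 1 <= j else 0.0
                    sc = ps + inner + right
                    # stacking: inner pair immediately adjacent
                    if k - 2 > i + 1 and choice[i + 1][k - 1] == k - 1:
                        sc += self.stack_bonus
                    if sc > b:
                        b, c = sc, k
                best[i][j] = b
                choice[i][j] = c
        structure = ["."] * n
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j:
                continue
            k = choice[i][j]
            if k == -1:
                stack.append((i + 1, j))
            else:
                structure[i], structure[k] = "(", ")"
                if k - 1 > i + 1:
                    stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
        return "".join(structure), -best[0][n - 1]


def default_folder() -> FoldingEngine:
    """ViennaRNA when importable, otherwise the bundled max-pairing fallback."""
    try:
        return ViennaFolder()
    except FoldingError:
        return MaxPairFolder()


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position; -1 for unpaired. Rejects unbalanced input."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"bad structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt
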