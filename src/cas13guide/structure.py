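"""RNA secondary structure prediction for Cas13d guides.

Two interchangeable folding engines are provided:

* ``"thermo"`` — the ViennaRNA thermodynamic nearest-neighbour model
  (minimum free energy in kcal/mol), used when the ``RNA`` python
  bindings are importable.  This is the engine used to build structure
  inputs for the efficiency model in production.
* ``"maxpair"`` — a self-contained Nussinov-style maximum base-pairing
  folder with a deterministic traceback.  Its "energy" is the proxy
  ``-1.0 * pair_count``.  It exists so that every part of the package
  (tests, simulations, the CLI) runs identically on machines without
  ViennaRNA.

Both return a :class:`FoldResult` (dot-bracket string + energy).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

RNA_ALPHABET = frozenset("ACGU")

#: canonical Watson-Crick pairs plus G.U wobble
_PAIRS = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")})


class EngineUnavailableError(RuntimeError):
    """Raised when the thermodynamic engine is requested but not importable."""


def _validate_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if not s:
        raise ValueError("empty sequence")
    if bad:
        raise ValueError(f"invalid RNA characters {sorted(bad)} in sequence")
    return s


@dataclass(frozen=True)
class FoldResult:
    """Predicted secondary structure of one RNA.

    Attributes
    ----------
    dot_bracket : str
        Structure in dot-bracket notation, same length as the sequence.
    mfe : float
        Minimum free energy (kcal/mol) for the thermodynamic engine, or
        ``-pair_count`` for the max-pairing fallback.  Never positive.
    """

    dot_bracket: str
    mfe: float

    def pair_map(self) -> dict[int, int]:
        """0-based partner index for every paired position (symmetric)."""
        stack: list[int] = []
        pairs: dict[int, int] = {}
        for i, c in enumerate(self.dot_bracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket string")
                j = stack.pop()
                pairs[i] = j
                pairs[j] = i
            elif c != ".":
                raise ValueError(f"invalid dot-bracket character {c!r}")
        if stack:
            raise ValueError("unbalanced dot-bracket string")
        return pairs

    @property
    def pair_count(self) -> int:
        return self.dot_bracket.count("(")


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def nussinov_fallback(seq: str, min_hairpin: int = 3) -> tuple[str, int]:
    """Maximum base-pairing structure with a minimum hairpin loop.

    Maximises the number of Watson-Crick + G.U pairs subject to a hairpin
    loop of at least ``min_hairpin`` unpaired bases.  Traceback is
    deterministic: within any interval the leftmost position pairs with
    the largest partner index that still achieves the optimum.

    Returns ``(dot_bracket, pair_count)``.
    """
    s = _validate_rna(seq)
    n = len(s)
    # dp[i][j] = max pairs in s[i..j] inclusive
    dp = [[0] * n for _ in range(n)]
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            for k in range(i + min_hairpin + 1, j + 1):
                if can_pair(s[i], s[k]):
                    inner = dp[i + 1][k - 1] if k - 1 > i else 0
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            dp[i][j] = best

    struct = ["."] * n

    def trace(i: int, j: int) -> None:
        while i < j:
            # pair i (smallest index first) with the largest partner k
            # that still achieves the optimum; otherwise leave i unpaired
            for k in range(j, i + min_hairpin, -1):
                if can_pair(s[i], s[k]):
                    inner = dp[i + 1][k - 1] if k - 1 > i else 0
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    if 1 + inner + right == dp[i][j]:
                        struct[i] = "("
                        struct[k] = ")"
                        if k - 1 > i:
                            trace(i + 1, k - 1)
                        i = k + 1
                        break
            else:
                i += 1

    if n > min_hairpin:
        trace(0, n - 1)
    return "".join(struct), struct.count("(")


@lru_cache(maxsize=1)
def _vienna():
    try:
        import RNA  # type: ignore
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise EngineUnavailableError(
            "ViennaRNA python bindings not importable; use engine='maxpair'"
        ) from exc
    return RNA


def fold_mfe(seq: str, engine: str = "thermo") -> FoldResult:
    """Fold one RNA sequence and return structure + energy.

    Parameters
    ----------
    seq : str
        RNA (or DNA; T is read as U) sequence, case-insensitive.
    engine : {"thermo", "maxpair"}
        ``"thermo"`` uses the ViennaRNA MFE model; ``"maxpair"`` the
        internal maximum-pairing folder with energy ``-pair_count``.
    """
    s = _validate_rna(seq)
    if engine == "thermo":
        RNA = _vienna()
        db, mfe = RNA.fold(s)
        return FoldResult(dot_bracket=db, mfe=float(mfe))
    if engine == "maxpair":
        db, npairs = nussinov_fallback(s)
        return FoldResult(dot_bracket=db, mfe=-1.0 * npairs)
    raise ValueError(f"unknown folding engine {engine!r}")


def crrna_energy(spacer: str, dr: str, engine: str = "thermo") -> float:
    """Folding energy of the full crRNA: direct repeat followed by spacer.

    The direct repeat (DR) is the constant scaffold 5' of the spacer; it
    must be supplied explicitly (it is vector-specific and not defaulted).
    """
    if not dr:
        raise ValueError(
            "direct-repeat sequence is required for crRNA energy; "
            "configure the DR used by your expression vector"
        )
    return fold_mfe(_validate_rna(dr) + _validate_rna(spacer), engine=engine).mfe


def default_engine() -> str:
    """``"thermo"`` when ViennaRNA is importable, else ``"maxpair"``."""
    try:
        _vienna()
    except EngineUnavailableError:
        return "maxpair"
    return "thermo"
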