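"""Model input encoding and LFC target normalization.

The regression target for the efficiency model is not the raw log2 fold
change but a squashed version of it: a customized sigmoid

    S(x) = 1 / (1 + exp(-n*x + b))

whose two parameters (n, b) are solved from two calibration constraints,
by default S(0) = 0.3 and S(-0.3) = 0.7.  This maps strongly depleted
guides (effective knockdown, LFC <= -0.5) close to 1 while stretching
the densely populated LFC interval [-0.3, 0] over a wide target range.

Guides are encoded as a pair of one-hot matrices — an L x 4 sequence
matrix (channels A, C, G, U) and an L x 3 structure matrix (dot-bracket
channels '.', '(', ')') — right-padded to a fixed model length L with a
binary validity mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import FoldResult, RNA_ALPHABET

SEQ_CHANNELS = "ACGU"
STRUCT_CHANNELS = ".()"

#: default model input length; fits both 22-nt and 27-nt guide libraries
DEFAULT_LENGTH = 30

#: default sigmoid calibration constraints, (x, S(x)) pairs
DEFAULT_CONSTRAINTS = ((0.0, 0.3), (-0.3, 0.7))

#: LFC at or below which a guide counts as an effective ("positive") guide
DEFAULT_LFC_THRESHOLD = -0.5


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters (n, b) of the target-normalization sigmoid."""

    n: float
    b: float

    def __call__(self, x):
        return lfc_to_target(x, self)


def solve_sigmoid_params(
    constraints: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_CONSTRAINTS,
) -> SigmoidParams:
    """Solve (n, b) from two (x, S) constraints.

    In logit space the sigmoid is linear: logit(S(x)) = n*x - b, so two
    constraints give an exact 2x2 linear system.  Raises ``ValueError``
    for degenerate constraints (equal x, or equal S which would make S
    constant and non-monotone).
    """
    (x1, s1), (x2, s2) = constraints
    for s in (s1, s2):
        if not 0.0 < s < 1.0:
            raise ValueError(f"constraint value {s} outside (0, 1)")
    if x1 == x2:
        raise ValueError("degenerate constraints: identical x values")
    l1 = math.log(s1 / (1.0 - s1))
    l2 = math.log(s2 / (1.0 - s2))
    n = (l1 - l2) / (x1 - x2)
    if n == 0.0:
        raise ValueError("constraints imply n = 0: sigmoid would not be strictly monotone")
    b = n * x1 - l1
    # closed form is exact; assert residual as a guard
    for x, s in constraints:
        resid = abs(1.0 / (1.0 + math.exp(-n * x + b)) - s)
        if resid > 1e-10:  # pragma: no cover - arithmetic guard
            raise ArithmeticError(f"sigmoid calibration residual {resid} > 1e-10")
    return SigmoidParams(n=n, b=b)


def lfc_to_target(x, params: SigmoidParams | None = None):
    """Normalize LFC(s) to the (0, 1) prediction target S(x).

    Strictly decreasing in x for the default calibration: stronger
    depletion (more negative LFC) maps closer to 1.
    Accepts scalars or numpy arrays.
    """
    if params is None:
        params = solve_sigmoid_params()
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(-params.n * x + params.b))
    return float(out) if out.ndim == 0 else out


def label_positive(lfc: float, threshold: float = DEFAULT_LFC_THRESHOLD) -> bool:
    """True iff the guide counts as effective: LFC <= threshold (inclusive)."""
    if lfc is None or (isinstance(lfc, float) and math.isnan(lfc)):
        raise ValueError("missing LFC; filter unmeasured guides before labeling")
    return bool(lfc <= threshold)


@dataclass(frozen=True)
class EncodedGuide:
    """Fixed-length tensor encoding of one guide.

    ``seq_onehot`` is L x 4 (A, C, G, U), ``struct_onehot`` is L x 3
    ('.', '(', ')'); rows beyond the guide length are all-zero and
    flagged by ``mask`` (1 = real position, 0 = padding).
    """

    seq_onehot: np.ndarray
    struct_onehot: np.ndarray
    mask: np.ndarray

    @property
    def length(self) -> int:
        return int(self.mask.sum())

    def decode(self) -> tuple[str, str]:
        """Recover (spacer, dot_bracket) from the one-hot matrices."""
        n = self.length
        seq = "".join(SEQ_CHANNELS[k] for k in self.seq_onehot[:n].argmax(axis=1))
        db = "".join(STRUCT_CHANNELS[k] for k in self.struct_onehot[:n].argmax(axis=1))
        return seq, db


def encode_guide(spacer: str, fold: FoldResult, L: int = DEFAULT_LENGTH) -> EncodedGuide:
    """One-hot encode a spacer and its predicted structure, padded to L."""
    s = spacer.upper().replace("T", "U")
    if set(s) - RNA_ALPHABET:
        raise ValueError(f"invalid RNA characters in spacer {spacer!r}")
    if len(s) != len(fold.dot_bracket):
        raise ValueError("fold was not computed on this spacer (length mismatch)")
    if len(s) > L:
        raise ValueError(
            f"spacer length {len(s)} exceeds model input length L={L}; raise L"
        )
    seq = np.zeros((L, 4), dtype=np.float64)
    struct = np.zeros((L, 3), dtype=np.float64)
    mask = np.zeros(L, dtype=np.float64)
    for i, (base, sym) in enumerate(zip(s, fold.dot_bracket)):
        seq[i, SEQ_CHANNELS.index(base)] = 1.0
        struct[i, STRUCT_CHANNELS.index(sym)] = 1.0
        mask[i] = 1.0
    return EncodedGuide(seq_onehot=seq, struct_onehot=struct, mask=mask)


def stack_encoded(guides: list[EncodedGuide]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack encoded guides into (B, L, 4), (B, L, 3), (B, L) arrays."""
    seq = np.stack([g.seq_onehot for g in guides])
    struct = np.stack([g.struct_onehot for g in guides])
    mask = np.stack([g.mask for g in guides])
    return seq, struct, mask
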