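"""Integrated-Gradients attribution for the guide-efficiency network.

For input x and baseline x' (default: the all-zero "no sequence"
encoding) the attribution of input coordinate i is

    IG_i = (x_i - x'_i) * (1/m) * sum_{s=1..m} dF/dx_i (x' + (s/m)(x - x'))

a right-Riemann approximation of the path integral.  As m grows the
attributions satisfy the completeness axiom, sum(IG) = F(x) - F(x');
the residual is recorded on every map.  Because padded positions are
zero in both input and baseline their attributions are exactly zero.

Position/nucleotide preference summaries average, at each position,
the attribution of the nucleotide actually observed there across many
guides — the view in which efficient Cas13d guides show their C/G
preference in the central window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .encoding import EncodedGuide


@dataclass
class AttributionMap:
    """Per-position, per-channel attributions for one guide."""

    values: np.ndarray          # L x 4 sequence-channel attributions
    struct_values: np.ndarray   # L x 3 structure-channel attributions
    baseline_score: float
    input_score: float
    steps: int

    @property
    def completeness_residual(self) -> float:
        total = self.values.sum() + self.struct_values.sum()
        return float(abs(total - (self.input_score - self.baseline_score)))


def _zero_baseline(guide: EncodedGuide) -> EncodedGuide:
    return EncodedGuide(
        seq_onehot=np.zeros_like(guide.seq_onehot),
        struct_onehot=np.zeros_like(guide.struct_onehot),
        mask=guide.mask.copy(),
    )


def integrated_gradients(model, guide: EncodedGuide,
                         baseline: EncodedGuide | None = None,
                         steps: int = 64) -> AttributionMap:
    """Integrated Gradients of the model output for one encoded guide.

    ``model`` is anything with a ``forward(seq, struct, mask, train=False)``
    returning a length-B tensor of scores (the trained CRNN, or a
    surrogate in tests).  The whole Riemann path is evaluated as one
    batch.
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    baseline = baseline or _zero_baseline(guide)
    if baseline.seq_onehot.shape != guide.seq_onehot.shape:
        raise ValueError("baseline shape differs from input shape")

    dx_seq = guide.seq_onehot - baseline.seq_onehot
    dx_struct = guide.struct_onehot - baseline.struct_onehot
    alphas = np.arange(1, steps + 1) / steps  # right-Riemann {1/m ... 1}

    seq_path = baseline.seq_onehot[None] + alphas[:, None, None] * dx_seq[None]
    struct_path = baseline.struct_onehot[None] + alphas[:, None, None] * dx_struct[None]
    mask = np.broadcast_to(guide.mask, (steps, len(guide.mask)))

    xs = nn.Tensor(seq_path, requires_grad=True)
    xt = nn.Tensor(struct_path, requires_grad=True)
    out = model.forward(xs, xt, mask, train=False)
    out.sum().backward()
    grad_seq = xs.grad.mean(axis=0)
    grad_struct = xt.grad.mean(axis=0)

    f_input = float(model.forward(
        nn.Tensor(guide.seq_onehot[None]), nn.Tensor(guide.struct_onehot[None]),
        guide.mask[None], train=False).data[0])
    f_base = float(model.forward(
        nn.Tensor(baseline.seq_onehot[None]), nn.Tensor(baseline.struct_onehot[None]),
        baseline.mask[None], train=False).data[0])

    return AttributionMap(
        values=dx_seq * grad_seq,
        struct_values=dx_struct * grad_struct,
        baseline_score=f_base,
        input_score=f_input,
        steps=steps,
    )


def position_importance(maps: list[AttributionMap], guides: list[EncodedGuide],
                        normalize: bool = False) -> np.ndarray:
    """Position × nucleotide summary: mean attribution of the observed base.

    Entry (p, c) averages, over guides carrying nucleotide c at position
    p, the attribution assigned to that observation.  With
    ``normalize=True`` the matrix is scaled to unit total absolute mass.
    """
    if not maps:
        raise ValueError("empty attribution-map list")
    if len(maps) != len(guides):
        raise ValueError("maps and guides differ in length")
    L = maps[0].values.shape[0]
    acc = np.zeros((L, 4))
    cnt = np.zeros((L, 4))
    for m, g in zip(maps, guides):
        if m.values.shape[0] != L:
            raise ValueError("attribution maps have mixed lengths")
        obs = g.seq_onehot
        acc += m.values * obs
        cnt += obs
    out = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    if normalize:
        mass = np.abs(out).sum()
        if mass > 0:
            out = out / mass
    return out
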