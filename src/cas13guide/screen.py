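"""Proliferation-screen analysis with explicit negative-control choices.

Counts are normalized by median-ratio size factors computed on a chosen
control set — all guides ("none"), non-targeting guides, or guides
targeting non-essential genes.  Guide-level log2 fold changes compare
mean end-point (t1) with mean start (t0) abundance.

Gene-level negative selection uses a light-weight mean-rank statistic
with a permutation null (a simplified stand-in for robust rank
aggregation): a gene's score is the mean rank of its guides' LFCs, and
its p-value is the tail probability of that score under seeded
resampling of guide ranks from a null pool, preserving the gene's guide
count.  The null pool is the chosen control set (all guides when no
controls are used) — this is how the control choice shapes which genes
look significant: against a non-targeting null every guide's
efficiency-coupled collateral depletion looks like signal, while a
non-essential-target null absorbs it.

The control benchmark sweeps FDR cutoffs and reports, per control
choice, the true positive rate on known essential genes and the false
positive rate on known non-essential genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

CONTROL_CHOICES = ("none", "non_targeting", "non_essential")
ANNOTATIONS = ("non_targeting", "non_essential_target", "other")


@dataclass
class ScreenMatrix:
    """Guides × samples count table with roles and control annotations."""

    counts: pd.DataFrame                  # index = guide ids, columns = samples
    sample_roles: dict[str, str]          # sample -> "t0" | "t1"
    control_annotation: pd.Series         # guide -> annotation
    gene_map: pd.Series                   # guide -> gene

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        roles = set(self.sample_roles.values())
        if not {"t0", "t1"} <= roles:
            raise ValueError("need at least one t0 and one t1 sample")
        for s in self.counts.columns:
            if s not in self.sample_roles:
                raise ValueError(f"sample {s!r} has no role")
        bad = set(self.control_annotation.unique()) - set(ANNOTATIONS)
        if bad:
            raise ValueError(f"unknown control annotations {sorted(bad)}")

    def samples(self, role: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_roles[s] == role]

    def guides_with_annotation(self, annotation: str) -> pd.Index:
        return self.control_annotation.index[self.control_annotation == annotation]


def read_count_matrix(path, t0_samples: list[str], t1_samples: list[str],
                      nonessential_genes: set[str] = frozenset(),
                      nt_gene: str = "non_targeting") -> ScreenMatrix:
    """Read a MAGeCK-count-style TSV (sgRNA, Gene, sample columns)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sgRNA", "Gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} (MAGeCK count dialect)")
    df = df.set_index("sgRNA")
    samples = list(t0_samples) + list(t1_samples)
    missing = [s for s in samples if s not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sample column(s) {missing}")
    gene_map = df["Gene"].astype(str)
    annotation = pd.Series(
        np.where(gene_map == nt_gene, "non_targeting",
                 np.where(gene_map.isin(nonessential_genes), "non_essential_target", "other")),
        index=df.index,
    )
    roles = {s: "t0" for s in t0_samples} | {s: "t1" for s in t1_samples}
    return ScreenMatrix(counts=df[samples].astype(float), sample_roles=roles,
                        control_annotation=annotation, gene_map=gene_map)


def write_count_matrix(screen: ScreenMatrix, path) -> None:
    out = screen.counts.copy()
    out.insert(0, "Gene", screen.gene_map)
    out.index.name = "sgRNA"
    out.reset_index().to_csv(path, sep="\t", index=False)


def _control_index(m: ScreenMatrix, control_set: str) -> pd.Index:
    if control_set == "none":
        return m.counts.index
    if control_set == "non_targeting":
        idx = m.guides_with_annotation("non_targeting")
    elif control_set == "non_essential":
        idx = m.guides_with_annotation("non_essential_target")
    else:
        raise ValueError(f"unknown control set {control_set!r}; choose from {CONTROL_CHOICES}")
    if len(idx) == 0:
        raise ValueError(
            f"control set {control_set!r} is empty; annotate guides with "
            f"'{'non_targeting' if control_set == 'non_targeting' else 'non_essential_target'}'"
        )
    return idx


def normalize_counts(m: ScreenMatrix, control_set: str = "none"
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Median-ratio normalization on the chosen control subset.

    Size factors are the per-sample median of count / geometric-mean
    ratios over control guides with all-positive counts; every sample is
    divided by its factor.  Returns (normalized counts, size factors).
    """
    ctrl = _control_index(m, control_set)
    sub = m.counts.loc[ctrl]
    pos = sub[(sub > 0).all(axis=1)]
    if pos.empty:
        raise ValueError("no control guide has positive counts in every sample")
    log_geo = np.log(pos).mean(axis=1)
    ratios = np.log(pos).sub(log_geo, axis=0)
    factors = np.exp(ratios.median(axis=0))
    return m.counts.div(factors, axis=1), factors


def guide_lfc(normalized: pd.DataFrame, sample_roles: dict[str, str],
              pseudocount: float = 1.0) -> pd.Series:
    """log2((mean t1 + pc) / (mean t0 + pc)) per guide."""
    t0 = [s for s in normalized.columns if sample_roles[s] == "t0"]
    t1 = [s for s in normalized.columns if sample_roles[s] == "t1"]
    if not t0 or not t1:
        raise ValueError("roles must include t0 and t1 samples")
    mean0 = normalized[t0].mean(axis=1)
    mean1 = normalized[t1].mean(axis=1)
    return np.log2((mean1 + pseudocount) / (mean0 + pseudocount)).rename("lfc")


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def gene_negative_selection(lfcs: pd.Series, gene_map: pd.Series,
                            n_perm: int = 10000, seed: int = 0,
                            control_guides: pd.Index | None = None,
                            min_guides: int = 2) -> pd.DataFrame:
    """Mean-rank negative-selection test with a permutation null.

    Ranks all guides by LFC ascending (strong depletion = low rank);
    a gene's score is its guides' mean rank.  The null resamples, per
    permutation, a same-sized set of ranks from ``control_guides``
    (all guides when None) without replacement.  p-values are the
    one-sided lower-tail probabilities with the +1 correction, so
    p >= 1/(n_perm+1); FDR is Benjamini-Hochberg across genes.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    # ranks are computed over every guide in `lfcs` (tested genes' guides
    # and control guides alike); genes tested are those in `gene_map`
    ranks = pd.Series(rankdata(lfcs.to_numpy()), index=lfcs.index)
    common = lfcs.index.intersection(gene_map.index)
    genes = gene_map.loc[common]

    pool = ranks.loc[control_guides.intersection(lfcs.index)].to_numpy() \
        if control_guides is not None else ranks.loc[common].to_numpy()
    if len(pool) < min_guides:
        raise ValueError("null pool smaller than the smallest tested gene")

    sizes = genes.value_counts()
    small = sizes[sizes < min_guides]
    if not small.empty:
        raise ValueError(f"gene(s) with fewer than {min_guides} guides: {list(small.index)[:5]}")

    rng = np.random.default_rng(seed)
    m = len(pool)
    null_by_size: dict[int, np.ndarray] = {}
    for s in sorted(set(sizes)):
        if s > m:
            raise ValueError(f"gene with {s} guides exceeds null pool size {m}")
        keys = rng.random((n_perm, m))
        idx = np.argpartition(keys, s - 1, axis=1)[:, :s]
        null_by_size[s] = np.sort(pool[idx].mean(axis=1))

    ranks_tested = ranks.loc[common]
    rows = []
    for gene, s in sizes.items():
        obs = float(ranks_tested[genes == gene].mean())
        null = null_by_size[int(s)]
        p = (1.0 + np.searchsorted(null, obs, side="right")) / (n_perm + 1.0)
        rows.append({"gene": gene, "score": obs, "p": min(p, 1.0)})
    res = pd.DataFrame(rows).set_index("gene").sort_values("score")
    res["fdr"] = _bh_fdr(res["p"].to_numpy())
    return res


def control_benchmark(screen: ScreenMatrix, essential_set: set[str],
                      nonessential_set: set[str],
                      fdr_grid=(0.01, 0.05, 0.1, 0.25),
                      n_perm: int = 2000, seed: int = 0) -> pd.DataFrame:
    """TPR/FPR of essential-gene detection per control choice per FDR cutoff.

    TPR = fraction of known essential genes called at fdr < cutoff;
    FPR = fraction of known non-essential genes called at fdr < cutoff.
    """
    if not essential_set or not nonessential_set:
        raise ValueError("truth sets must be non-empty")
    if essential_set & nonessential_set:
        raise ValueError("essential and non-essential truth sets overlap")

    targeting = screen.control_annotation.index[screen.control_annotation != "non_targeting"]
    rows = []
    for control in CONTROL_CHOICES:
        normalized, _ = normalize_counts(screen, control)
        lfc = guide_lfc(normalized, screen.sample_roles)
        if control == "none":
            pool = None
        elif control == "non_targeting":
            pool = screen.guides_with_annotation("non_targeting")
        else:
            pool = screen.guides_with_annotation("non_essential_target")
        res = gene_negative_selection(lfc, screen.gene_map.loc[targeting],
                                      n_perm=n_perm, seed=seed, control_guides=pool)
        ess = res.loc[res.index.isin(essential_set), "fdr"]
        non = res.loc[res.index.isin(nonessential_set), "fdr"]
        for cutoff in fdr_grid:
            rows.append({
                "control": control, "fdr_cutoff": cutoff,
                "tpr": float((ess < cutoff).mean()) if len(ess) else float("nan"),
                "fpr": float((non < cutoff).mean()) if len(non) else float("nan"),
            })
    return pd.DataFrame(rows)
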