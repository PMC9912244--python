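"""Guide library I/O and tiling-guide design.

Cas13d guides (spacers) are stored internally in the RNA alphabet
(A/C/G/U); DNA is accepted on input and T is normalized to U.  Tables
are read and written in two dialects:

* ``canonical`` — this package's own round-trippable TSV
  (guide_id, spacer, gene, target_type, region, lfc);
* ``mageck`` — the MAGeCK sgRNA-summary-style layout
  (columns ``sgrna``, ``Gene``, ``LFC``).

Guide design follows the tiling strategy used for Cas13d proliferation
libraries: enumerate every window of the configured length along each
transcript, reject windows whose cloning oligo carries a BsmBI site
(CGTCTC / GAGACG on either strand) and windows that are not unique
within the supplied sequence set (Hamming distance up to a configured
mismatch count, both strands), then pick guides that hit the greatest
number of the gene's transcripts first, breaking ties with a seeded RNG.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .structure import RNA_ALPHABET

logger = logging.getLogger(__name__)

TARGET_TYPES = ("mRNA", "lncRNA", "circRNA", "non_targeting")
REGIONS = ("CDS", "UTR5", "UTR3", "noncoding", "NA")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_TO_DNA = str.maketrans("U", "T")


@dataclass
class GuideRecord:
    """One guide: spacer, target annotation and measured depletion.

    ``lfc`` is the log2 fold change of guide abundance between the end
    point and the start of a screen (negative = depleted); ``None``
    means not measured / unparseable.
    """

    guide_id: str
    spacer: str
    gene: str
    target_type: str = "mRNA"
    region: str = "NA"
    lfc: float | None = None

    def __post_init__(self) -> None:
        self.spacer = self.spacer.upper().replace("T", "U")
        if not self.spacer:
            raise ValueError(f"guide {self.guide_id!r}: empty spacer")
        bad = set(self.spacer) - RNA_ALPHABET
        if bad:
            raise ValueError(f"guide {self.guide_id!r}: invalid spacer characters {sorted(bad)}")
        if self.target_type not in TARGET_TYPES:
            raise ValueError(f"guide {self.guide_id!r}: unknown target_type {self.target_type!r}")
        if self.region not in REGIONS:
            raise ValueError(f"guide {self.guide_id!r}: unknown region {self.region!r}")
        if self.lfc is not None and math.isnan(self.lfc):
            self.lfc = None

    @property
    def spacer_dna(self) -> str:
        return self.spacer.translate(_RNA_TO_DNA)


@dataclass
class DesignRules:
    """Parameters of the tiling-guide design procedure."""

    guide_length: int = 22
    forbidden_motifs: tuple[str, ...] = ("CGTCTC", "GAGACG")  # BsmBI sites
    max_mismatch_for_uniqueness: int = 1
    guides_per_gene: int = 15

    def __post_init__(self) -> None:
        if self.guide_length < 15:
            raise ValueError("guide_length must be >= 15")
        self.forbidden_motifs = tuple(m.upper() for m in self.forbidden_motifs)
        for m in self.forbidden_motifs:
            if set(m) - set("ACGT"):
                raise ValueError(f"forbidden motif {m!r} is not uppercase DNA")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Ids are taken up to the first whitespace; sequences are uppercased
    with U/T preserved as read.  A malformed header (sequence data
    before any '>' line) raises with the offending line number.
    """
    path = Path(path)
    out: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if current is not None:
                    out[current] = "".join(chunks)
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                current = header.split()[0]
                chunks = []
            else:
                if current is None:
                    raise ValueError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                chunks.append(line.strip().upper())
    if current is not None:
        out[current] = "".join(chunks)
    if not out:
        logger.warning("FASTA file %s contained no records", path)
    return out


_MAGECK_COLUMNS = {"sgrna": "guide_id", "Gene": "gene", "LFC": "lfc"}
_CANONICAL_COLUMNS = ["guide_id", "spacer", "gene", "target_type", "region", "lfc"]


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    # keep "NA" literal: missingness is decided per-column downstream
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_guide_table(path: str | Path, dialect: str = "canonical") -> list[GuideRecord]:
    """Read a guide table in the ``canonical`` or ``mageck`` dialect.

    Rows whose LFC fails to parse are kept with ``lfc=None`` and logged,
    never silently dropped.  A missing mandatory column raises a schema
    error listing the expected columns.
    """
    df = _read_table(path)
    if dialect == "mageck":
        missing = [c for c in ("sgrna", "Gene", "LFC") if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing mandatory column(s) {missing}; "
                f"mageck dialect expects columns ['sgrna', 'Gene', 'LFC']"
            )
        df = df.rename(columns=_MAGECK_COLUMNS)
        if "sequence" in df.columns:
            df = df.rename(columns={"sequence": "spacer"})
        if "spacer" not in df.columns:
            df["spacer"] = df["guide_id"]  # MAGeCK libraries often use the sequence as id
    elif dialect == "canonical":
        missing = [c for c in _CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing mandatory column(s) {missing}; "
                f"canonical dialect expects columns {_CANONICAL_COLUMNS}"
            )
    else:
        raise ValueError(f"unknown table dialect {dialect!r}")

    records: list[GuideRecord] = []
    flagged: list[str] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        gid = str(row["guide_id"])
        if gid in seen:
            raise ValueError(f"{path}: duplicate guide_id {gid!r}")
        seen.add(gid)
        raw_lfc = row.get("lfc")
        lfc: float | None
        try:
            lfc = float(raw_lfc)
            if math.isnan(lfc):
                lfc = None
                flagged.append(gid)
        except (TypeError, ValueError):
            lfc = None
            flagged.append(gid)
        records.append(
            GuideRecord(
                guide_id=gid,
                spacer=str(row["spacer"]),
                gene=str(row["gene"]),
                target_type=str(row.get("target_type", "mRNA") or "mRNA"),
                region=str(row.get("region", "NA") or "NA"),
                lfc=lfc,
            )
        )
    if flagged:
        logger.warning(
            "%s: %d row(s) with missing/unparseable LFC kept with lfc=None: %s",
            path, len(flagged), ", ".join(flagged[:10]),
        )
    return records


def write_guide_table(records: Iterable[GuideRecord], path: str | Path) -> None:
    """Write records in the canonical TSV dialect (round-trip exact)."""
    rows = []
    for r in records:
        rows.append({
            "guide_id": r.guide_id,
            "spacer": r.spacer,
            "gene": r.gene,
            "target_type": r.target_type,
            "region": r.region,
            "lfc": "NA" if r.lfc is None else repr(r.lfc),
        })
    pd.DataFrame(rows, columns=_CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def reverse_complement_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def _contains_motif(window_dna: str, motifs: tuple[str, ...]) -> bool:
    rc = reverse_complement_dna(window_dna)
    return any(m in window_dna or m in rc for m in motifs)


def _hamming_at_most(a: str, b: str, k: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def _count_matches(window: str, haystacks: Iterable[str], k: int) -> int:
    """Occurrences of `window` in the haystacks (both strands, <=k mismatches)."""
    n = len(window)
    rc = reverse_complement_dna(window)
    hits = 0
    for seq in haystacks:
        for i in range(len(seq) - n + 1):
            sub = seq[i:i + n]
            if _hamming_at_most(window, sub, k) or _hamming_at_most(rc, sub, k):
                hits += 1
    return hits


def design_guides(
    transcripts: Mapping[str, Mapping[str, str]],
    rules: DesignRules | None = None,
    seed: int = 0,
) -> list[GuideRecord]:
    """Design tiling guides for each gene.

    Parameters
    ----------
    transcripts : mapping gene -> {transcript_id: sequence}
        DNA or RNA sequences; uniqueness is screened against this set
        only (not a full genome index).
    rules : DesignRules
    seed : int
        Seeds the tie-breaking RNG; the whole procedure is deterministic
        given (transcripts, rules, seed).

    Returns guides (spacer = reverse complement of the target window)
    sorted by gene; each guide hits the greatest possible number of its
    gene's transcripts ("common" guides are picked first).
    """
    rules = rules or DesignRules()
    k = rules.guide_length
    rng = np.random.default_rng(seed)

    # DNA rendering of every transcript, for the uniqueness scan
    dna_by_gene = {
        g: {t: s.upper().replace("U", "T") for t, s in txs.items()}
        for g, txs in transcripts.items()
    }

    out: list[GuideRecord] = []
    for gene in sorted(dna_by_gene):
        txs = dna_by_gene[gene]
        usable = {t: s for t, s in txs.items() if len(s) >= k}
        if not usable:
            logger.warning(
                "gene %s skipped: all transcripts shorter than guide length %d", gene, k
            )
            continue
        # candidate windows and how many of the gene's transcripts each hits
        window_hits: dict[str, int] = {}
        window_pos: dict[str, tuple[str, int]] = {}
        for tx in sorted(usable):
            seq = usable[tx]
            for i in range(len(seq) - k + 1):
                w = seq[i:i + k]
                if w not in window_pos:
                    window_pos[w] = (tx, i)
        for w in window_pos:
            window_hits[w] = sum(1 for s in usable.values() if w in s)

        other_seqs = [
            s for g2, txs2 in dna_by_gene.items() if g2 != gene for s in txs2.values()
        ]
        candidates = []
        for w, hits in window_hits.items():
            if _contains_motif(w, rules.forbidden_motifs):
                continue
            if set(w) - set("ACGT"):
                continue
            # off-target: any (mismatch-tolerant) hit in another gene rejects
            if other_seqs and _count_matches(w, other_seqs, rules.max_mismatch_for_uniqueness) > 0:
                continue
            candidates.append(w)

        # fill from the highest transcript-hit count downward, random ties
        chosen: list[str] = []
        for hits in sorted({window_hits[w] for w in candidates}, reverse=True):
            tier = sorted(w for w in candidates if window_hits[w] == hits)
            rng.shuffle(tier)
            for w in tier:
                if len(chosen) >= rules.guides_per_gene:
                    break
                chosen.append(w)
            if len(chosen) >= rules.guides_per_gene:
                break

        for idx, w in enumerate(chosen, start=1):
            tx, pos0 = window_pos[w]
            spacer = reverse_complement_dna(w)  # guide is complementary to the target
            out.append(
                GuideRecord(
                    guide_id=f"{gene}_g{idx}_{tx}_{pos0 + 1}",  # 1-based position
                    spacer=spacer,
                    gene=gene,
                )
            )
    return out
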