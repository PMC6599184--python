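"""Short-query ungapped nucleotide search with Karlin-Altschul statistics.

Host miRNAs are ~22 nt. Searching them against a bacterial gene catalog for
complementary sites uses the short-query nucleotide scoring regime: match +1,
mismatch -3, exact 7-mer seeds, ungapped extension. Significance follows
Karlin-Altschul theory: a raw score S maps to a bit score
B = (lambda*S - ln K) / ln 2 and an expectation E = m*n*2^(-B) over a search
space of query length m times total catalog length n. With the ungapped
constants lambda = 1.374 nats and K = 0.711, perfect matches of 15/16/17/18 nt
score 30.2/32.2/34.2/36.2 bits.

Because queries are short the alignment window on any diagonal is at most the
query length, so "extension" here computes the exact maximum-scoring ungapped
segment containing a seed word on each seeded diagonal rather than a heuristic
X-drop walk (the x_drop_raw parameter is retained for interface completeness;
with exact extension it cannot change results for short queries).

E-values carry no finite-size length adjustment and are labelled uncorrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DataError, GeneCatalog, OtuTable, normalize_dna

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    s = seq.upper()
    if set(s) - set("ACGT"):
        raise DataError(f"cannot reverse-complement non-ACGT sequence {seq!r}")
    return s.translate(_COMPLEMENT)[::-1]


def solve_lambda(
    reward: float,
    penalty: float,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    tol: float = 1e-9,
) -> float:
    """Solve sum_ij p_i q_j exp(lambda * s(i,j)) = 1 for lambda > 0.

    For a match/mismatch scheme with uniform base frequencies this reduces to
    0.25*exp(lambda*reward) + 0.75*exp(lambda*penalty) = 1. Bisection to
    ``tol``. Requires a negative expected score per aligned pair (penalty < 0
    and reward small enough), otherwise no positive root exists.
    """
    p = np.asarray(base_freqs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("base_freqs must be a probability vector")
    p_match = float((p * p).sum())
    expected = p_match * reward + (1 - p_match) * penalty
    if expected >= 0 or reward <= 0:
        raise ValueError(
            "expected score per pair must be negative with a positive reward"
        )

    def f(lam: float) -> float:
        return (p_match * math.exp(lam * reward)
                + (1 - p_match) * math.exp(lam * penalty) - 1.0)

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - defensive
            raise RuntimeError("no positive root found")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ScoringParams:
    """Short-query nucleotide scoring and significance constants.

    lambda_ is the Karlin-Altschul scale in nats and K the search-space
    constant for the ungapped +1/-3 scheme; both are the published ungapped
    values. ``validate`` re-derives lambda by root-finding and rejects a
    mismatch beyond 1e-3.
    """

    match_reward: int = 1
    mismatch_penalty: int = -3
    lambda_: float = 1.374
    K: float = 0.711
    word_size: int = 7
    e_max: float = 10.0
    x_drop_raw: int = 6
    min_identity: float = 0.90
    require_query_coverage: bool = False

    def validate(self) -> None:
        lam = solve_lambda(self.match_reward, self.mismatch_penalty)
        if abs(lam - self.lambda_) > 1e-3:
            raise ValueError(
                f"lambda {self.lambda_} inconsistent with scoring scheme "
                f"(root-finding gives {lam:.6f})"
            )

    def score(self, matches: int, length: int) -> int:
        return (matches * self.match_reward
                + (length - matches) * self.mismatch_penalty)


DEFAULT_PARAMS = ScoringParams()


def bit_score(raw_score: float, params: ScoringParams = DEFAULT_PARAMS) -> float:
    """Bit score B = (lambda*S - ln K) / ln 2."""
    return (params.lambda_ * raw_score - math.log(params.K)) / math.log(2.0)


def evalue(
    bits: float, query_len: int, db_len: int,
    params: ScoringParams = DEFAULT_PARAMS,
) -> float:
    """Uncorrected expectation E = m * n * 2^(-B).

    m is the query length and n the total catalog length; no finite-size
    length adjustment is applied.
    """
    if query_len <= 0 or db_len <= 0:
        raise ValueError("query and database lengths must be positive")
    return float(query_len) * float(db_len) * math.pow(2.0, -bits)


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped miRNA-vs-gene alignment.

    Query coordinates are on the miRNA as given; subject coordinates are on
    the forward strand of the gene (0-based, half-open). ``strand`` is '-'
    when the miRNA matches the reverse complement of the subject interval
    (the biologically expected orientation for a target site).
    """

    mirna_id: str
    gene_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    length: int
    identities: int
    raw_score: int
    bit_score: float
    evalue: float

    def __post_init__(self) -> None:
        assert self.identities <= self.length
        assert self.q_end - self.q_start == self.length
        assert self.s_end - self.s_start == self.length

    @property
    def identity(self) -> float:
        return self.identities / self.length


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_BASE_LUT = np.zeros(256, dtype=np.int64)
for _b, _v in _CODE.items():
    _BASE_LUT[ord(_b)] = _v


def _word_codes(arr: np.ndarray, w: int) -> np.ndarray:
    """Rolling base-4 integer codes of every w-mer (vectorized)."""
    if arr.size < w:
        return np.empty(0, dtype=np.int64)
    codes = _BASE_LUT[arr]
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    powers = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    return windows @ powers


def _best_segment_with_seed(
    match: np.ndarray, word_size: int, reward: int, penalty: int
) -> tuple[int, int, int, int] | None:
    """Exact best-scoring segment of a 0/1 match vector containing a full
    word_size run of matches.

    Returns (start, end, score, identities) or None when no seed run exists.
    Ties resolve to the shortest, then leftmost segment (deterministic).
    """
    L = match.size
    if L < word_size:
        return None
    # positions where a word_size run of matches starts
    run = np.convolve(match, np.ones(word_size, dtype=int), mode="valid")
    seed_starts = np.flatnonzero(run == word_size)
    if seed_starts.size == 0:
        return None
    scores = np.where(match == 1, reward, penalty)
    prefix = np.concatenate([[0], np.cumsum(scores)])
    mprefix = np.concatenate([[0], np.cumsum(match)])
    best = None  # (score, length, start, end, idents) max score, min length
    for i in range(L):
        # earliest seed run starting at >= i
        k = np.searchsorted(seed_starts, i)
        if k == seed_starts.size:
            break
        jmin = seed_starts[k] + word_size  # segment must reach end of a run
        for j in range(jmin, L + 1):
            sc = prefix[j] - prefix[i]
            if best is None or sc > best[0] or (
                sc == best[0] and (j - i) < best[1]
            ):
                best = (sc, j - i, i, j, mprefix[j] - mprefix[i])
    if best is None:  # pragma: no cover - seed guarantees a segment
        return None
    sc, _, i, j, idents = best
    return i, j, sc, idents


def find_hits(
    mirna_seq: str,
    gene_seq: str,
    params: ScoringParams = DEFAULT_PARAMS,
    mirna_id: str = "query",
    gene_id: str = "subject",
    db_len: int | None = None,
) -> list[AlignmentHit]:
    """All seeded ungapped alignments of a miRNA against one gene.

    Exact ``word_size``-mer seeds are located on the gene and its reverse
    complement; each seeded diagonal yields the exact maximum-scoring ungapped
    segment containing a seed. Same-diagonal duplicates collapse to the best
    segment. Hits with identity fraction below ``params.min_identity`` are
    dropped; with ``require_query_coverage`` the alignment must additionally
    span >= min_identity of the query.

    ``db_len`` sets the search-space size for E-values (defaults to the gene
    length so single-gene calls are self-contained).
    """
    q = normalize_dna(mirna_seq, "query")
    s = normalize_dna(gene_seq, "subject")
    if len(q) < params.word_size:
        raise DataError(
            f"query shorter than word size {params.word_size}"
        )
    n_db = db_len if db_len is not None else len(s)
    qa = _encode(q)
    hits: list[AlignmentHit] = []
    w = params.word_size

    for strand in "+-":
        target = s if strand == "+" else revcomp(s)
        ta = _encode(target)
        if len(target) < w:
            continue
        # seed positions: diagonals where query and target share a w-mer
        qcodes = _word_codes(qa, w)
        qmap: dict[int, list[int]] = {}
        for qi, code in enumerate(qcodes):
            qmap.setdefault(int(code), []).append(qi)
        tcodes = _word_codes(ta, w)
        hit_pos = np.flatnonzero(np.isin(tcodes, qcodes))
        diagonals: set[int] = set()
        for ti in hit_pos:
            for qi in qmap[int(tcodes[ti])]:
                diagonals.add(int(ti) - qi)
        for d in sorted(diagonals):
            # overlap of query [0, len(q)) with target [d, d+len(q))
            q_lo = max(0, -d)
            q_hi = min(len(q), len(target) - d)
            if q_hi - q_lo < w:
                continue
            match = (qa[q_lo:q_hi] == ta[q_lo + d:q_hi + d]).astype(int)
            seg = _best_segment_with_seed(
                match, w, params.match_reward, params.mismatch_penalty
            )
            if seg is None:
                continue
            i, j, raw, idents = seg
            q0, q1 = q_lo + i, q_lo + j
            t0, t1 = q0 + d, q1 + d
            if strand == "+":
                s0, s1 = t0, t1
            else:
                s0, s1 = len(s) - t1, len(s) - t0
            length = q1 - q0
            if idents / length < params.min_identity:
                continue
            if (params.require_query_coverage
                    and length < params.min_identity * len(q)):
                continue
            b = bit_score(raw, params)
            hits.append(AlignmentHit(
                mirna_id=mirna_id, gene_id=gene_id,
                q_start=q0, q_end=q1, s_start=s0, s_end=s1,
                strand=strand, length=length, identities=idents,
                raw_score=raw, bit_score=b,
                evalue=evalue(b, len(q), n_db, params),
            ))
    hits.sort(key=lambda h: (-h.raw_score, h.strand, h.s_start))
    return hits


def search_catalog(
    mirnas: dict[str, str],
    catalog: GeneCatalog,
    params: ScoringParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Search every miRNA against every catalog gene.

    Returns the hit table (one row per alignment with E <= ``params.e_max``)
    sorted by (miRNA, bit score descending), with the best hit per
    (miRNA, gene) pair flagged. E-values use the total catalog length as the
    database size.
    """
    if len(catalog) == 0:
        raise DataError("empty gene catalog")
    db_len = catalog.total_length
    w = params.word_size

    # combined seed-word index over all queries (both query orientations are
    # covered by scanning gene forward + revcomp inside find_hits; prefilter
    # genes by shared w-mers to skip the quadratic work on non-matching genes)
    norm_mirnas = {m: normalize_dna(seq, f"miRNA {m!r}")
                   for m, seq in mirnas.items()}
    qword_list: list[np.ndarray] = []
    for seq in norm_mirnas.values():
        qword_list.append(_word_codes(_encode(seq), w))
        qword_list.append(_word_codes(_encode(revcomp(seq)), w))
    qwords = np.unique(np.concatenate(qword_list))

    rows = []
    for gid in catalog.gene_ids:
        gseq = catalog.sequences[gid]
        gcodes = _word_codes(_encode(gseq), w)
        if not np.isin(gcodes, qwords).any():
            continue
        for mid, mseq in norm_mirnas.items():
            for h in find_hits(mseq, gseq, params, mirna_id=mid,
                               gene_id=gid, db_len=db_len):
                if h.evalue <= params.e_max:
                    rows.append(h)

    df = pd.DataFrame([{
        "mirna_id": h.mirna_id, "gene_id": h.gene_id,
        "q_start": h.q_start, "q_end": h.q_end,
        "s_start": h.s_start, "s_end": h.s_end, "strand": h.strand,
        "length": h.length, "identities": h.identities,
        "raw_score": h.raw_score,
        "bit_score": round(h.bit_score, 1), "evalue": h.evalue,
    } for h in rows], columns=[
        "mirna_id", "gene_id", "q_start", "q_end", "s_start", "s_end",
        "strand", "length", "identities", "raw_score", "bit_score", "evalue",
    ])
    if len(df):
        df = df.sort_values(
            ["mirna_id", "bit_score"], ascending=[True, False]
        ).reset_index(drop=True)
        best = df.groupby(["mirna_id", "gene_id"])["raw_score"].transform("max")
        df["best_for_pair"] = df["raw_score"] == best
    else:
        df["best_for_pair"] = pd.Series(dtype=bool)
    return df


# ---------------------------------------------------------------------------
# taxonomy collapse of hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationTarget:
    """A (miRNA, taxon) pair proposed for correlation testing.

    ``level`` records how the catalog lineage was mapped into the 16S table:
    directly at the genus level, collapsed from a family dominated by a single
    genus, or expanded to the OTUs of the parent genus for species-level hits.
    """

    mirna_id: str
    taxon_key: str
    level: str  # genus | genus_collapsed_from_family | otu
    gene_id: str
    bit_score: float
    evalue: float
    annotation_id: str = "NA"


def _genus_observed(otu_table: OtuTable, genus: str) -> bool:
    return any(l.genus == genus for l in otu_table.lineages)


def _family_dominant_genus(
    otu_table: OtuTable, family: str, threshold: float
) -> str | None:
    """Genus holding >= threshold of the family's 16S counts, if any.

    Mirrors the rule that a family-level catalog hit is only usable when the
    family is effectively a single genus in the 16S data (e.g. a family whose
    counts are >= 99% one genus).
    """
    idx = [i for i, l in enumerate(otu_table.lineages) if l.family == family]
    if not idx:
        return None
    totals: dict[str, float] = {}
    fam_total = 0.0
    for i in idx:
        c = float(otu_table.counts[:, i].sum())
        fam_total += c
        g = otu_table.lineages[i].genus
        if g is not None:
            totals[g] = totals.get(g, 0.0) + c
    if fam_total == 0:
        return None
    for g, c in totals.items():
        if c / fam_total >= threshold:
            return g
    return None


def assign_hit_taxon(
    hit: AlignmentHit | pd.Series,
    catalog: GeneCatalog,
    otu_table: OtuTable,
    dominance_threshold: float = 0.99,
) -> list[CorrelationTarget]:
    """Map one alignment hit to zero or more correlation targets.

    A gene without lineage yields nothing (the catalog's unclassified
    fraction). Species-level lineages map to every OTU of the parent genus;
    genus-level lineages map to the genus when it appears in the 16S table;
    family-level lineages collapse to a genus only when that genus holds
    >= ``dominance_threshold`` of the family's 16S counts.
    """
    if isinstance(hit, pd.Series):
        gene_id = str(hit["gene_id"])
        mirna_id = str(hit["mirna_id"])
        bits = float(hit["bit_score"])
        ev = float(hit["evalue"])
    else:
        gene_id, mirna_id = hit.gene_id, hit.mirna_id
        bits, ev = round(hit.bit_score, 1), hit.evalue
    lin = catalog.lineage_of(gene_id)
    ann = catalog.annotations.get(gene_id, "NA")
    if lin is None:
        return []

    def make(key: str, level: str) -> CorrelationTarget:
        return CorrelationTarget(
            mirna_id=mirna_id, taxon_key=key, level=level, gene_id=gene_id,
            bit_score=bits, evalue=ev, annotation_id=ann,
        )

    deepest = lin.deepest_rank
    if deepest == "species" and lin.genus is not None:
        otus = [otu_table.otu_ids[i]
                for i, l in enumerate(otu_table.lineages)
                if l.genus == lin.genus]
        return [make(o, "otu") for o in otus]
    if lin.genus is not None:
        if _genus_observed(otu_table, lin.genus):
            return [make(lin.genus, "genus")]
        return []
    if lin.family is not None:
        g = _family_dominant_genus(otu_table, lin.family, dominance_threshold)
        if g is not None:
            return [make(g, "genus_collapsed_from_family")]
        return []
    return []


def assign_all(
    hits: pd.DataFrame,
    catalog: GeneCatalog,
    otu_table: OtuTable,
    dominance_threshold: float = 0.99,
) -> list[CorrelationTarget]:
    """Taxonomy-collapse every row of a hit table; unclassified genes drop."""
    targets: list[CorrelationTarget] = []
    for _, row in hits.iterrows():
        targets.extend(
            assign_hit_taxon(row, catalog, otu_table, dominance_threshold)
        )
    return targets
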