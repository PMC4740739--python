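"""Minimal nucleotide local-similarity engine with Karlin-Altschul E-values.

The engine is deliberately BLAST-shaped: exact k-mer seeds over both strands
of the database, co-diagonal seed clustering, ungapped X-drop extension, then
banded gapped (affine Smith-Waterman) refinement of surviving high-scoring
segments.  Statistics follow the ungapped Karlin-Altschul model::

    bit score  = (lambda * S - ln K) / ln 2
    E-value    = K * m * n * exp(-lambda * S)

with S the raw alignment score, m the query length and n the *total*
database length (summed over sequences) — the convention the 1e-5 cutoff of
database search tools is calibrated against.

A 12-column tabular reader/writer (query, subject, %identity, length,
mismatches, gap opens, q.start, q.end, s.start, s.end, evalue, bit score;
1-based inclusive in-file) lets precomputed hits from an external search
program substitute for the internal engine anywhere downstream.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import banded_sw, ungapped_extend
from .containers import ScaffoldSet
from .errors import ConfigurationError, InputError, ParseError

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_SEEDABLE = np.zeros(256, dtype=bool)
for _b in "ACGT":
    _SEEDABLE[ord(_b)] = True

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# cells below which gapped refinement runs the full DP matrix rather than a band
_FULL_DP_CELLS = 250_000


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, seedable): 0..3/4 base codes and uppercase-ACGT flags."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw], _SEEDABLE[raw]


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring and statistics.

    match/mismatch/gap_open/gap_extend are raw-score increments (a gap of
    length L costs gap_open + L*gap_extend).  lam (lambda) and kappa are the
    Karlin-Altschul parameters for the match/mismatch scheme; k is the seed
    word size; xdrop the extension drop-off; e_cutoff the maximum reported
    E-value; band the half-width (in diagonals) of gapped refinement.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    kappa: float = 0.46
    k: int = 11
    xdrop: int = 20
    e_cutoff: float = 1e-5
    band: int = 16

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ConfigurationError("require match > 0 > mismatch")
        if self.k < 4:
            raise ConfigurationError("seed word size k must be >= 4")
        if self.e_cutoff <= 0:
            raise ConfigurationError("e_cutoff must be > 0")
        if self.gap_open > 0 or self.gap_extend >= 0:
            raise ConfigurationError("gap penalties must be negative")

    def bit_score(self, raw: int) -> float:
        return (self.lam * raw - math.log(self.kappa)) / math.log(2.0)

    def e_value(self, raw: int, m: int, n: int) -> float:
        return self.kappa * m * n * math.exp(-self.lam * raw)

    def min_raw_score(self, m: int, n: int) -> float:
        """Smallest raw score whose E-value passes the cutoff."""
        return (math.log(self.kappa * m * n) - math.log(self.e_cutoff)) / self.lam


@dataclass
class HomologyHit:
    """One local alignment between a query region and a database sequence.

    Coordinates are 0-based half-open on the forward strand of both query
    and subject; ``strand`` is '-' when the query matches the subject's
    reverse complement.
    """

    query: str
    subject: str
    taxon: str = ""
    db_class: str = ""            # "bacterial" | "animal"
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    strand: str = "+"
    raw_score: int = 0
    bit_score: float = 0.0
    e_value: float = 0.0
    identity: float = 0.0
    aln_length: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    def shifted(self, offset: int) -> "HomologyHit":
        """Hit with query coordinates lifted by ``offset`` (window -> scaffold)."""
        return replace(self, q_start=self.q_start + offset,
                       q_end=self.q_end + offset)


class SeedIndex:
    """Exact k-mer positions over both strands of a database.

    Soft-masked (lowercase) and N positions never seed; they are still
    present in the stored code arrays so extension can run through them
    (N scores as a mismatch against everything).
    """

    def __init__(self, db: ScaffoldSet, params: ScoringParams | None = None,
                 db_class: str = ""):
        if len(db) == 0:
            raise InputError("cannot index an empty database")
        self.params = params or ScoringParams()
        self.db = db
        self.db_class = db_class
        self.names = db.names
        self.total_length = db.total_length
        k = self.params.k

        self.codes: list[list[np.ndarray]] = []  # [seq][strand 0=+,1=-]
        kmers, seqi, strands, poss = [], [], [], []
        for si, (name, seq) in enumerate(db):
            fwd_codes, fwd_seed = encode(seq)
            rc = revcomp(seq)
            rev_codes, rev_seed = encode(rc)
            self.codes.append([fwd_codes, rev_codes])
            for strand, (codes, seedable) in enumerate(
                    [(fwd_codes, fwd_seed), (rev_codes, rev_seed)]):
                pos, vals = _kmer_values(codes, seedable, k)
                kmers.append(vals)
                seqi.append(np.full(len(vals), si, dtype=np.int32))
                strands.append(np.full(len(vals), strand, dtype=np.int8))
                poss.append(pos.astype(np.int32))
        allk = np.concatenate(kmers) if kmers else np.empty(0, np.int64)
        order = np.argsort(allk, kind="stable")
        self.kmers = allk[order]
        self.seq_index = np.concatenate(seqi)[order]
        self.strand = np.concatenate(strands)[order]
        self.pos = np.concatenate(poss)[order]

    def n_seeds(self, strand: str = "+") -> int:
        want = 0 if strand == "+" else 1
        return int(np.sum(self.strand == want))

    def lookup(self, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ranges [lo, hi) into the sorted seed arrays for each query k-mer."""
        lo = np.searchsorted(self.kmers, vals, side="left")
        hi = np.searchsorted(self.kmers, vals, side="right")
        return lo, hi


def _kmer_values(codes: np.ndarray, seedable: np.ndarray, k: int):
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    vals = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    c64 = codes.astype(np.int64)
    for t in range(k):
        vals = (vals << 2) | c64[t:t + n]
        ok &= seedable[t:t + n]
    idx = np.nonzero(ok)[0]
    return idx, vals[idx]


def build_index(db: ScaffoldSet, params: ScoringParams | None = None,
                db_class: str = "") -> SeedIndex:
    """Build the seed index for a (pre-masked) database."""
    return SeedIndex(db, params, db_class)


def search(query: str, index: SeedIndex, params: ScoringParams | None = None,
           query_name: str = "query") -> list[HomologyHit]:
    """Seed-and-extend search of one query against the index.

    Returns non-redundant hits with E <= e_cutoff, sorted by ascending
    E-value then descending bit score.  Queries shorter than the word size
    return an empty list.
    """
    params = params or index.params
    k = params.k
    if len(query) < k:
        return []
    qcodes, qseed = encode(query)
    qpos, qvals = _kmer_values(qcodes, qseed, k)
    if len(qvals) == 0:
        return []
    lo, hi = index.lookup(qvals)
    counts = hi - lo
    nz = counts > 0
    if not nz.any():
        return []
    starts = lo[nz]
    c = counts[nz]
    m = int(c.sum())
    # grouped arange: indices into the index's seed arrays for every match
    offs = np.arange(m) - np.repeat(np.cumsum(c) - c, c)
    take = np.repeat(starts, c) + offs
    qq = np.repeat(qpos[nz], c)
    seqi = index.seq_index[take]
    strand = index.strand[take]
    spos = index.pos[take]
    diag = spos.astype(np.int64) - qq

    order = np.lexsort((qq, diag, strand, seqi))
    # python lists: the per-seed loop below is interpreter-bound
    seqi, strand, spos, qq, diag = (a[order].tolist() for a in
                                    (seqi, strand, spos, qq, diag))

    m_q = len(query)
    n_db = index.total_length
    s_min = params.min_raw_score(m_q, n_db)
    trigger = max(0.5 * s_min, float(k))

    raw_hits: list[HomologyHit] = []
    i = 0
    total = len(qq)
    while i < total:
        si, st, dg = seqi[i], strand[i], diag[i]
        j = i
        covered_end = -1
        scodes = index.codes[si][st]
        while j < total and seqi[j] == si and strand[j] == st and diag[j] == dg:
            if qq[j] >= covered_end:
                q0u, q1u, score = ungapped_extend(
                    qcodes, scodes, qq[j], spos[j], k,
                    params.match, params.mismatch, params.xdrop)
                covered_end = q1u
                if score >= trigger:
                    hit = _gapped_refine(qcodes, scodes, q0u, q1u, dg,
                                         params)
                    if hit is not None:
                        raw_hits.append(_finalize(hit, index, si, st,
                                                  query_name, m_q, params))
            j += 1
        i = j

    hits = [h for h in raw_hits if h.e_value <= params.e_cutoff]
    hits = _remove_redundant(hits)
    hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.subject,
                             h.q_start, h.s_start))
    return hits


def _gapped_refine(qcodes, scodes, q0u, q1u, diag, params):
    """Banded affine SW around an ungapped HSP; returns region-level fields."""
    pad = 2 * params.xdrop
    rq0 = max(0, q0u - pad)
    rq1 = min(len(qcodes), q1u + pad)
    rs0 = max(0, q0u + diag - pad)
    rs1 = min(len(scodes), q1u + diag + pad)
    nq = rq1 - rq0
    ns = rs1 - rs0
    if nq <= 0 or ns <= 0:
        return None
    if nq * ns <= _FULL_DP_CELLS:
        dlo, dhi = -nq, ns
    else:
        center = diag - (rs0 - rq0)  # seed diagonal in region coordinates
        dlo, dhi = center - params.band, center + params.band
    res = banded_sw(qcodes[rq0:rq1], scodes[rs0:rs1], dlo, dhi,
                    params.match, params.mismatch,
                    params.gap_open, params.gap_extend)
    score, a0, a1, b0, b1, n_match, n_mismatch, gap_opens, aln_len = res
    if score <= 0:
        return None
    return dict(score=int(score), q_start=rq0 + a0, q_end=rq0 + a1,
                s_start=rs0 + b0, s_end=rs0 + b1, n_match=int(n_match),
                n_mismatch=int(n_mismatch), gap_opens=int(gap_opens),
                aln_length=int(aln_len))


def _finalize(h: dict, index: SeedIndex, si: int, st: int,
              query_name: str, m_q: int, params: ScoringParams) -> HomologyHit:
    name = index.names[si]
    slen = len(index.db[name])
    s0, s1 = h["s_start"], h["s_end"]
    if st == 1:  # coordinates were on the reverse complement
        s0, s1 = slen - h["s_end"], slen - h["s_start"]
    raw = h["score"]
    return HomologyHit(
        query=query_name, subject=name, taxon=index.db.taxon_of(name),
        db_class=index.db_class,
        q_start=h["q_start"], q_end=h["q_end"], s_start=s0, s_end=s1,
        strand="+" if st == 0 else "-",
        raw_score=raw, bit_score=params.bit_score(raw),
        e_value=params.e_value(raw, m_q, index.total_length),
        identity=h["n_match"] / h["aln_length"] if h["aln_length"] else 0.0,
        aln_length=h["aln_length"], mismatches=h["n_mismatch"],
        gap_opens=h["gap_opens"])


def _remove_redundant(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Overlapping hits on the same subject/strand keep the highest-scoring."""
    hits = sorted(hits, key=lambda h: (-h.raw_score, h.e_value, h.subject,
                                       h.q_start))
    kept: list[HomologyHit] = []
    for h in hits:
        redundant = False
        for g in kept:
            if (g.subject == h.subject and g.strand == h.strand
                    and h.q_start < g.q_end and g.q_start < h.q_end
                    and h.s_start < g.s_end and g.s_start < h.s_end):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def search_all(queries: ScaffoldSet, index: SeedIndex,
               params: ScoringParams | None = None) -> list[HomologyHit]:
    """Search every sequence of ``queries``; hits keep their query's name."""
    out: list[HomologyHit] = []
    for name, seq in queries:
        out.extend(search(seq, index, params, query_name=name))
    return out


# ---------------------------------------------------------------------------
# tabular (BLAST outfmt-6 dialect) I/O

_TAB_COLUMNS = ["query", "subject", "pident", "length", "mismatches",
                "gap_opens", "q_start", "q_end", "s_start", "s_end",
                "evalue", "bitscore"]


def write_tabular(hits: list[HomologyHit], path: str | os.PathLike) -> None:
    """Write 12-column tabular hits (1-based inclusive coordinates in-file).

    Reverse-strand hits are written with subject start > subject end, the
    standard tabular convention.
    """
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            fh.write("\t".join([
                h.query, h.subject, f"{100.0 * h.identity:.2f}",
                str(h.aln_length), str(h.mismatches), str(h.gap_opens),
                str(h.q_start + 1), str(h.q_end), str(ss), str(se),
                f"{h.e_value:.3e}", f"{h.bit_score:.2f}"]) + "\n")


def read_tabular(path: str | os.PathLike,
                 params: ScoringParams | None = None,
                 db_class: str = "",
                 taxa: dict[str, str] | None = None) -> list[HomologyHit]:
    """Read 12-column tabular hits back to the internal convention.

    1-based inclusive in-file coordinates become 0-based half-open; a subject
    range with start > end marks a reverse-strand hit.  The raw score is
    recovered from the bit score via the Karlin-Altschul relation.
    """
    params = params or ScoringParams()
    taxa = taxa or {}
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                pident = float(parts[2])
                length = int(parts[3])
                mism = int(parts[4])
                gaps = int(parts[5])
                qs, qe = int(parts[6]), int(parts[7])
                ss, se = int(parts[8]), int(parts[9])
                evalue = float(parts[10])
                bit = float(parts[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            strand = "+" if ss <= se else "-"
            if strand == "-":
                ss, se = se, ss
            raw = round((bit * math.log(2.0) + math.log(params.kappa))
                        / params.lam)
            hits.append(HomologyHit(
                query=parts[0], subject=parts[1],
                taxon=taxa.get(parts[1], parts[1]), db_class=db_class,
                q_start=qs - 1, q_end=qe, s_start=ss - 1, s_end=se,
                strand=strand, raw_score=int(raw), bit_score=bit,
                e_value=evalue, identity=pident / 100.0, aln_length=length,
                mismatches=mism, gap_opens=gaps))
    return hits
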