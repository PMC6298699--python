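"""Three-letter bisulfite alignment and strand-resolved methylation calling.

The reference is a single small circular plasmid, so alignment is exact and
exhaustive: a read is compared against every circular offset of both
bisulfite-converted reference strands under the three-letter transform
(reference C->T against C->T-collapsed reads for plus-origin molecules;
reference G->A against the G->A-collapsed reverse complement for minus-origin
molecules) and placed at the minimum-Hamming-distance offset.  Reads whose
best score is tied across two or more distinct placements are discarded as
ambiguous; reads whose best score exceeds the mismatch budget are discarded
as no-hits.

``three_letter_align`` is the per-read reference implementation of that scan.
``align_reads`` is an exact batch equivalent: it seeds candidate placements
with ``max_mismatch + 1`` disjoint k-mers per read (by pigeonhole, any
placement within the mismatch budget matches at least one seed exactly) and
verifies candidates by full Hamming count, so it returns the same placements
as the exhaustive scan for every read it declares valid, and the same
valid/invalid decisions throughout.

Methylation calls follow the Bismark convention: at a reference cytosine
covered by a read of matching origin strand, an unconverted C (G on the minus
strand in plus-frame coordinates) is a methylated call and a converted T (A)
is an unmethylated call; any other base is no call.  Calls carry the
reference context (CpG / CHG / CHH) and trinucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .simdata import PlasmidSpec, encode, decode, revcomp, _C, _G, _T, _A, _BASE_IDX

__all__ = [
    "Placement",
    "Call",
    "three_letter_align",
    "brute_force_align",
    "align_reads",
    "extract_calls",
    "aggregate_report",
    "count_calls_batch",
    "estimate_frequencies",
    "label_cis_trans",
    "quantify_reads",
    "default_max_mismatch",
]


@dataclass(frozen=True)
class Placement:
    """A read placement on the circular reference."""

    read_id: str
    position: int          # 1-based plus-strand start of the covered window
    strand: str            # origin strand: '+' or '-'
    mismatches: int
    valid: bool
    reason: str = "ok"     # 'ok' | 'no_hit' | 'ambiguous'


class Call(NamedTuple):
    pos: int
    strand: str
    context: str
    trinucleotide: str
    methylated: bool


def default_max_mismatch(read_length: int) -> int:
    """Default mismatch budget: 5% of the read length, rounded up."""
    return int(np.ceil(0.05 * read_length))


def _ct(a: np.ndarray) -> np.ndarray:
    b = a.copy()
    b[b == _C] = _T
    return b


def _ga(a: np.ndarray) -> np.ndarray:
    b = a.copy()
    b[b == _G] = _A
    return b


def _revcomp_rows(mat: np.ndarray) -> np.ndarray:
    from .simdata import _COMP_LUT

    return _COMP_LUT[mat[:, ::-1]]


class _RefIndex:
    """Transformed doubled references plus seed k-mer tables for one plasmid."""

    def __init__(self, plasmid: PlasmidSpec):
        self.plasmid = plasmid
        arr = encode(plasmid.sequence)
        self.L = arr.size
        doubled = np.concatenate([arr, arr])
        self.doubled = doubled
        self.ct = _ct(doubled)
        self.ga = _ga(doubled)
        self._kmer_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    def kmer_table(self, which: str, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Sorted 2-bit-packed k-mer codes (positions 0..L-1) of a transform."""
        key = (which, k)
        if key not in self._kmer_cache:
            ref = self.ct if which == "ct" else self.ga
            idx = _BASE_IDX[ref].astype(np.uint64)
            powers = (np.uint64(4) ** np.arange(k, dtype=np.uint64))[::-1]
            win = np.lib.stride_tricks.sliding_window_view(idx, k)[: self.L]
            codes = win @ powers
            order = np.argsort(codes, kind="stable")
            self._kmer_cache[key] = (codes[order], order.astype(np.int64))
        return self._kmer_cache[key]


_index_cache: dict[int, _RefIndex] = {}


def _get_index(plasmid: PlasmidSpec) -> _RefIndex:
    key = id(plasmid)
    idx = _index_cache.get(key)
    if idx is None or idx.plasmid is not plasmid:
        _index_cache.clear()
        idx = _RefIndex(plasmid)
        _index_cache[key] = idx
    return idx


def _scan_one(read_enc: np.ndarray, ref_doubled: np.ndarray, L: int) -> np.ndarray:
    """Hamming distance of a transformed read at every circular offset."""
    n = read_enc.size
    win = np.lib.stride_tricks.sliding_window_view(ref_doubled, n)[:L]
    return (win != read_enc).sum(axis=1)


def brute_force_align(
    read: str,
    plasmid: PlasmidSpec,
    max_mismatch: int | None = None,
    read_id: str = "read",
) -> Placement:
    """Exhaustive scan over all 2*length transformed circular placements."""
    if len(read) > plasmid.length:
        raise ValueError("read longer than plasmid")
    if max_mismatch is None:
        max_mismatch = default_max_mismatch(len(read))
    idx = _get_index(plasmid)
    r_plus = _ct(encode(read))
    r_minus = _ga(encode(revcomp(read)))
    mm_plus = _scan_one(r_plus, idx.ct, idx.L)
    mm_minus = _scan_one(r_minus, idx.ga, idx.L)
    all_mm = np.concatenate([mm_plus, mm_minus])
    best = int(all_mm.min())
    hits = np.flatnonzero(all_mm == best)
    if best > max_mismatch:
        return Placement(read_id, 0, "+", best, False, "no_hit")
    if hits.size > 1:
        return Placement(read_id, 0, "+", best, False, "ambiguous")
    h = int(hits[0])
    strand = "+" if h < idx.L else "-"
    pos = (h % idx.L) + 1
    return Placement(read_id, pos, strand, best, True, "ok")


def three_letter_align(
    read: str,
    plasmid: PlasmidSpec,
    max_mismatch: int | None = None,
    read_id: str = "read",
) -> Placement:
    """Align one bisulfite read to the circular reference (exhaustive scan)."""
    return brute_force_align(read, plasmid, max_mismatch, read_id)


def align_reads(
    bases: np.ndarray,
    plasmid: PlasmidSpec,
    max_mismatch: int | None = None,
) -> dict[str, np.ndarray]:
    """Batch-align equal-length reads; exact equivalent of the exhaustive scan.

    Parameters
    ----------
    bases : (n_reads, read_length) ascii uint8 matrix.

    Returns
    -------
    dict of arrays: position0 (0-based plus start), minus (origin strand flag),
    mismatches, valid, reason code (0 ok / 1 no_hit / 2 ambiguous).
    """
    n, rl = bases.shape
    if rl > plasmid.length:
        raise ValueError("read length exceeds plasmid length")
    if max_mismatch is None:
        max_mismatch = default_max_mismatch(rl)
    idx = _get_index(plasmid)
    L = idx.L

    n_seeds = max_mismatch + 1
    k = min(31, rl // n_seeds)
    if k < 8:
        # short reads: exhaustive per-read scan is already cheap
        pos0 = np.zeros(n, dtype=np.int64)
        minus = np.zeros(n, dtype=bool)
        mism = np.zeros(n, dtype=np.int64)
        valid = np.zeros(n, dtype=bool)
        reason = np.zeros(n, dtype=np.int8)
        for i in range(n):
            p = brute_force_align(decode(bases[i]), plasmid, max_mismatch)
            pos0[i], minus[i] = p.position - 1, p.strand == "-"
            mism[i], valid[i] = p.mismatches, p.valid
            reason[i] = {"ok": 0, "no_hit": 1, "ambiguous": 2}[p.reason]
        return dict(position0=pos0, minus=minus, mismatches=mism, valid=valid, reason=reason)

    seed_offsets = np.arange(n_seeds) * k
    powers = (np.uint64(4) ** np.arange(k, dtype=np.uint64))[::-1]

    reads_ct = _ct(bases)
    reads_garc = _ga(_revcomp_rows(bases))

    cand_read, cand_pos, cand_strand = [], [], []
    for strand_flag, (reads_t, which) in enumerate(
        [(reads_ct, "ct"), (reads_garc, "ga")]
    ):
        sorted_codes, sorted_pos = idx.kmer_table(which, k)
        ridx = _BASE_IDX[reads_t].astype(np.uint64)
        for o in seed_offsets:
            codes = ridx[:, o : o + k] @ powers
            lo = np.searchsorted(sorted_codes, codes, side="left")
            hi = np.searchsorted(sorted_codes, codes, side="right")
            counts = hi - lo
            if counts.max(initial=0) == 0:
                continue
            reps = np.repeat(np.arange(n), counts)
            flat = np.concatenate(
                [sorted_pos[a:b] for a, b in zip(lo, hi) if b > a]
            ) if counts.sum() else np.array([], dtype=np.int64)
            cand_read.append(reps)
            cand_pos.append((flat - o) % L)
            cand_strand.append(np.full(reps.size, strand_flag, dtype=np.int8))

    pos0 = np.zeros(n, dtype=np.int64)
    minus = np.zeros(n, dtype=bool)
    mism = np.full(n, rl + 1, dtype=np.int64)
    valid = np.zeros(n, dtype=bool)
    reason = np.ones(n, dtype=np.int8)  # default no_hit

    if not cand_read:
        return dict(position0=pos0, minus=minus, mismatches=mism, valid=valid, reason=reason)

    cr = np.concatenate(cand_read)
    cp = np.concatenate(cand_pos)
    cs = np.concatenate(cand_strand)
    key = (cr * 2 + cs) * L + cp
    uniq, first = np.unique(key, return_index=True)
    cr, cp, cs = cr[first], cp[first], cs[first]

    # verify candidates by full Hamming count, chunked for memory
    mm = np.empty(cr.size, dtype=np.int64)
    offs = np.arange(rl)
    for sflag, reads_t, ref_t in ((0, reads_ct, idx.ct), (1, reads_garc, idx.ga)):
        sel = np.flatnonzero(cs == sflag)
        for lo_i in range(0, sel.size, 200_000):
            ss = sel[lo_i : lo_i + 200_000]
            win = ref_t[cp[ss, None] + offs]
            mm[ss] = (win != reads_t[cr[ss]]).sum(axis=1)

    # best placement per read; tie across distinct placements -> ambiguous
    order = np.lexsort((cp, cs, mm, cr))
    cr_o, mm_o = cr[order], mm[order]
    firsts = np.flatnonzero(np.r_[True, cr_o[1:] != cr_o[:-1]])
    best_rows = order[firsts]
    best_reads = cr_o[firsts]
    best_mm = mm_o[firsts]
    # second-best per read (if any) to detect ties
    has_second = np.zeros(best_reads.size, dtype=bool)
    second_mm = np.full(best_reads.size, np.iinfo(np.int64).max)
    nexts = firsts + 1
    in_range = nexts < cr_o.size
    same_read = np.zeros(best_reads.size, dtype=bool)
    same_read[in_range] = cr_o[nexts[in_range]] == best_reads[in_range]
    has_second = same_read
    second_mm[has_second] = mm_o[nexts[has_second]]

    pos0[best_reads] = cp[best_rows]
    minus[best_reads] = cs[best_rows] == 1
    mism[best_reads] = best_mm
    tied = has_second & (second_mm == best_mm)
    ok = (best_mm <= max_mismatch) & ~tied
    valid[best_reads] = ok
    reason[best_reads] = np.where(ok, 0, np.where(tied, 2, 1))
    return dict(position0=pos0, minus=minus, mismatches=mism, valid=valid, reason=reason)


# ---------------------------------------------------------------------------
# reference context

def reference_contexts(plasmid: PlasmidSpec) -> pd.DataFrame:
    """Context and trinucleotide of every reference cytosine on both strands."""
    arr = encode(plasmid.sequence)
    L = arr.size
    seq = plasmid.sequence
    rows = []
    for p0 in range(L):
        if arr[p0] == _C:  # plus-strand cytosine
            n1, n2 = seq[(p0 + 1) % L], seq[(p0 + 2) % L]
            ctx = "CpG" if n1 == "G" else ("CHG" if n2 == "G" else "CHH")
            rows.append((p0 + 1, "+", ctx, seq[p0] + n1 + n2))
        if arr[p0] == _G:  # minus-strand cytosine at this plus position
            n1, n2 = seq[(p0 - 1) % L], seq[(p0 - 2) % L]
            ctx = "CpG" if n1 == "C" else ("CHG" if n2 == "C" else "CHH")
            tri = revcomp(seq[(p0 - 2) % L] + seq[(p0 - 1) % L] + seq[p0])
            rows.append((p0 + 1, "-", ctx, tri))
    return pd.DataFrame(rows, columns=["pos", "strand", "context", "trinucleotide"])


# ---------------------------------------------------------------------------
# per-read calls (reference implementation)

def extract_calls(
    placement: Placement, read: str, plasmid: PlasmidSpec
) -> list[Call]:
    """Per-cytosine methylation calls from one placed read.

    Plus-origin reads call at reference-C positions (C = methylated,
    T = unmethylated); minus-origin reads call at reference-G positions in
    plus-frame coordinates (G = methylated, A = unmethylated).  Other bases
    yield no call.
    """
    if not placement.valid:
        raise ValueError("placement is not valid")
    L = plasmid.length
    seq = plasmid.sequence
    ctx = reference_contexts(plasmid).set_index(["pos", "strand"])
    p0 = placement.position - 1
    window = read if placement.strand == "+" else revcomp(read)
    calls: list[Call] = []
    for o, base in enumerate(window):
        pos0 = (p0 + o) % L
        ref = seq[pos0]
        if placement.strand == "+" and ref == "C":
            if base == "C":
                meth = True
            elif base == "T":
                meth = False
            else:
                continue
            c = ctx.loc[(pos0 + 1, "+")]
            calls.append(Call(pos0 + 1, "+", c["context"], c["trinucleotide"], meth))
        elif placement.strand == "-" and ref == "G":
            if base == "G":
                meth = True
            elif base == "A":
                meth = False
            else:
                continue
            c = ctx.loc[(pos0 + 1, "-")]
            calls.append(Call(pos0 + 1, "-", c["context"], c["trinucleotide"], meth))
    return calls


def aggregate_report(calls: Sequence[Call]) -> pd.DataFrame:
    """Sum per-read calls into a per-cytosine report (CX-report dialect)."""
    if not calls:
        return pd.DataFrame(
            columns=["pos", "strand", "context", "trinucleotide",
                     "count_methylated", "count_unmethylated"]
        ).astype({"pos": int, "count_methylated": int, "count_unmethylated": int})
    df = pd.DataFrame(calls, columns=["pos", "strand", "context", "trinucleotide", "methylated"])
    g = (
        df.groupby(["pos", "strand", "context", "trinucleotide"], as_index=False)
        .agg(
            count_methylated=("methylated", "sum"),
            count_unmethylated=("methylated", lambda s: int((~s.astype(bool)).sum())),
        )
    )
    g["count_methylated"] = g["count_methylated"].astype(int)
    return g.sort_values(["pos", "strand"], ignore_index=True)


# ---------------------------------------------------------------------------
# batch calling

def count_calls_batch(
    bases: np.ndarray,
    alignment: dict[str, np.ndarray],
    plasmid: PlasmidSpec,
) -> pd.DataFrame:
    """CytosineReport from a batch alignment (vectorised call counting).

    Exactly equivalent to running ``extract_calls`` + ``aggregate_report``
    over every valid placement.
    """
    L = plasmid.length
    arr = encode(plasmid.sequence)
    doubled = np.concatenate([arr, arr])
    rl = bases.shape[1]
    offs = np.arange(rl)

    meth_p = np.zeros(L, dtype=np.int64)
    unmeth_p = np.zeros(L, dtype=np.int64)
    meth_m = np.zeros(L, dtype=np.int64)
    unmeth_m = np.zeros(L, dtype=np.int64)

    valid = alignment["valid"]
    for minus_origin in (False, True):
        sel = np.flatnonzero(valid & (alignment["minus"] == minus_origin))
        for lo in range(0, sel.size, 100_000):
            ss = sel[lo : lo + 100_000]
            p0 = alignment["position0"][ss]
            posmat = (p0[:, None] + offs) % L
            refwin = doubled[p0[:, None] + offs]
            rd = bases[ss]
            if minus_origin:
                rd = _revcomp_rows(rd)
                ref_c = refwin == _G
                meth_mask = ref_c & (rd == _G)
                unmeth_mask = ref_c & (rd == _A)
                np.add.at(meth_m, posmat[meth_mask], 1)
                np.add.at(unmeth_m, posmat[unmeth_mask], 1)
            else:
                ref_c = refwin == _C
                meth_mask = ref_c & (rd == _C)
                unmeth_mask = ref_c & (rd == _T)
                np.add.at(meth_p, posmat[meth_mask], 1)
                np.add.at(unmeth_p, posmat[unmeth_mask], 1)

    ctx = reference_contexts(plasmid)
    pos_idx = ctx["pos"].to_numpy() - 1
    is_plus = (ctx["strand"] == "+").to_numpy()
    cm = np.where(is_plus, meth_p[pos_idx], meth_m[pos_idx])
    cu = np.where(is_plus, unmeth_p[pos_idx], unmeth_m[pos_idx])
    out = ctx.copy()
    out["count_methylated"] = cm
    out["count_unmethylated"] = cu
    out = out[(out["count_methylated"] + out["count_unmethylated"]) > 0]
    return out.sort_values(["pos", "strand"], ignore_index=True)


# ---------------------------------------------------------------------------
# frequencies and labels

def estimate_frequencies(
    report: pd.DataFrame,
    min_coverage: int = 10,
    conversion_rate: float | None = None,
) -> pd.DataFrame:
    """Per-cytosine estimated methylation frequencies from a CytosineReport.

    Sites below ``min_coverage`` are flagged missing (frequency NaN), never
    reported as 0.  If ``conversion_rate`` is given, a background-corrected
    frequency ``max(0, (raw - (1 - rate)) / rate)`` is added; the raw column
    is always present.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    out = report.copy()
    cov = out["count_methylated"] + out["count_unmethylated"]
    out["coverage"] = cov
    freq = out["count_methylated"] / cov.replace(0, np.nan)
    out["missing"] = cov < min_coverage
    out["freq"] = freq.where(~out["missing"], np.nan)
    if conversion_rate is not None:
        if not 0.0 < conversion_rate <= 1.0:
            raise ValueError("conversion_rate must be in (0, 1]")
        corrected = (out["freq"] - (1.0 - conversion_rate)) / conversion_rate
        out["freq_corrected"] = corrected.clip(lower=0.0)
    return out


def estimated_background(report: pd.DataFrame) -> float:
    """Pooled apparent methylation rate at non-CpG cytosines.

    With no non-CpG methylation in the system, this estimates the combined
    bisulfite non-conversion and sequencing-error background directly from
    the data, as commonly done when a conversion control is available.
    """
    sub = report[report["context"] != "CpG"]
    tot = int(sub["count_methylated"].sum() + sub["count_unmethylated"].sum())
    if tot == 0:
        raise ValueError("no non-CpG calls to estimate the background from")
    return float(sub["count_methylated"].sum() / tot)


def label_cis_trans(table: pd.DataFrame, plasmid: PlasmidSpec) -> pd.DataFrame:
    """Attach cis/trans and target/non-target labels to a per-cytosine table.

    Cis is the protospacer/PAM-containing strand; the target dyad comprises
    the cis-strand C at ``target_cpg_pos`` and its minus-strand partner at
    ``target_cpg_pos + 1``.
    """
    L = plasmid.length
    pos = table["pos"].to_numpy()
    if ((pos < 1) | (pos > L)).any():
        bad = pos[(pos < 1) | (pos > L)]
        raise ValueError(f"positions outside [1, {L}]: {bad[:5]}")
    out = table.copy()
    cis_strand = plasmid.protospacer_strand
    out["cis_trans"] = np.where(out["strand"] == cis_strand, "cis", "trans")
    t = plasmid.target_cpg_pos
    tgt_plus = (out["pos"] == t) & (out["strand"] == "+")
    tgt_minus = (out["pos"] == ((t % L) + 1)) & (out["strand"] == "-")
    out["target"] = tgt_plus | tgt_minus
    return out


def quantify_reads(
    readset_or_bases,
    plasmid: PlasmidSpec,
    max_mismatch: int | None = None,
    min_coverage: int = 10,
    conversion_rate: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full quantification: align, call, aggregate, estimate, label.

    Returns (CytosineReport, SiteMethylationTable); the site table is
    restricted to CpG-context cytosines.
    """
    bases = getattr(readset_or_bases, "bases", readset_or_bases)
    alignment = align_reads(bases, plasmid, max_mismatch=max_mismatch)
    report = count_calls_batch(bases, alignment, plasmid)
    table = estimate_frequencies(report, min_coverage, conversion_rate)
    table = label_cis_trans(table, plasmid)
    site_table = table[table["context"] == "CpG"].reset_index(drop=True)
    return report, site_table
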