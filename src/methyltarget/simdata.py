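"""Synthetic reporter plasmid, condition profiles and bisulfite read simulation.

This module generates the study system entirely in silico: a ~4 kb circular
plasmid carrying one sgRNA protospacer + NGG PAM, a single target CpG dyad
embedded in an FspI site at a configurable gap from the PAM, a second
(non-target) FspI site, a SacI linearisation site, and a configurable number
of isolated non-target CpG dyads.  Ground-truth per-strand methylation
frequencies come from parametric condition profiles (linker-length series and
methyltransferase point mutants) plus a Beta-distributed off-target baseline,
and directional bisulfite reads are drawn from both strands with imperfect
conversion and uniform substitution error.

Coordinates are 1-based, inclusive, and circular: position ``length + 1``
wraps to 1.  The gap convention is the number of nucleotides strictly between
the last PAM base and the C of the target CpG on the cis (PAM-containing)
strand, counted 3' of the PAM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterator

import numpy as np
import yaml
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "PlasmidSpec",
    "ConditionProfile",
    "ReadSet",
    "LayoutError",
    "build_plasmid",
    "condition_profile",
    "load_conditions",
    "get_condition",
    "sample_offtarget_frequencies",
    "make_truth",
    "simulate_bisulfite_reads",
    "count_cpg_dyads",
    "revcomp",
    "derive_seed",
]

# ---------------------------------------------------------------------------
# sequence helpers

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_A, _C, _G, _T = (ord(b) for b in "ACGT")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ascii -> 0..3 index (A,C,G,T); 255 for anything else
_BASE_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i

_COMP_LUT = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGT", b"TGCA"):
    _COMP_LUT[_x] = _y


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an ascii uint8 array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def count_cpg_dyads(sequence: str) -> int:
    """Number of 5'-CG-3' dyads in a circular sequence (wrap included)."""
    if not sequence:
        return 0
    return (sequence + sequence[0]).count("CG")


def derive_seed(master: int, offset: int) -> int:
    """Derive a stage seed from a master seed by a fixed affine offset."""
    return (int(master) * 100_003 + 7919 * int(offset) + offset) % (2**31 - 1)


class LayoutError(ValueError):
    """Raised when the requested plasmid layout cannot be satisfied."""


# ---------------------------------------------------------------------------
# plasmid

@dataclass(frozen=True)
class PlasmidSpec:
    """A circular reporter plasmid with annotated functional elements.

    All positions are 1-based on the plus strand; the protospacer/PAM strand
    (cis) is the plus strand.  ``target_cpg_pos`` is the position of the C of
    the target CpG dyad on the cis strand; its dyad partner C sits on the
    minus strand at ``target_cpg_pos + 1``.
    """

    name: str
    sequence: str
    protospacer_start: int
    protospacer_strand: str
    pam_end: int
    target_cpg_pos: int
    gap: int
    nontarget_cpg_positions: tuple[int, ...]
    restriction_sites: tuple[tuple[str, int, str], ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nontarget_cpg_positions"] = list(self.nontarget_cpg_positions)
        d["restriction_sites"] = [list(s) for s in self.restriction_sites]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlasmidSpec":
        return cls(
            name=d["name"],
            sequence=d["sequence"],
            protospacer_start=int(d["protospacer_start"]),
            protospacer_strand=d["protospacer_strand"],
            pam_end=int(d["pam_end"]),
            target_cpg_pos=int(d["target_cpg_pos"]),
            gap=int(d["gap"]),
            nontarget_cpg_positions=tuple(int(p) for p in d["nontarget_cpg_positions"]),
            restriction_sites=tuple((s[0], int(s[1]), s[2]) for s in d["restriction_sites"]),
        )


_PROTOSPACER_LEN = 20
_FSPI = "TGCGCA"   # blunt cutter, CpG at third base
_SACI = "GAGCTC"   # linearises, no internal CpG
_SNABI = "TACGTA"  # blunt cutter, CpG at third base


def _strip_cpg(arr: np.ndarray, rng: np.random.Generator) -> None:
    """Remove every circular CG dinucleotide in place (G -> A or T)."""
    n = arr.size
    while True:
        nxt = np.roll(arr, -1)
        hits = np.flatnonzero((arr == _C) & (nxt == _G))
        if hits.size == 0:
            return
        repl = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=hits.size)
        arr[(hits + 1) % n] = repl


def _strip_motif(arr: np.ndarray, motif: str) -> None:
    """Break every circular occurrence of a CpG-free motif in place.

    The last C of the motif is changed to A, which cannot create a CG dyad.
    Used to keep the random backbone free of spontaneous SacI sites so the
    designed restriction layout is exactly the annotated one.
    """
    n = arr.size
    m = encode(motif)
    k = m.size
    last_c = motif.rfind("C")
    while True:
        win = np.lib.stride_tricks.sliding_window_view(
            np.concatenate([arr, arr[: k - 1]]), k
        )
        hits = np.flatnonzero((win == m).all(axis=1))
        if hits.size == 0:
            return
        arr[(hits[0] + last_c) % n] = _A


def build_plasmid(
    length: int = 4000,
    n_nontarget_cpg: int = 241,
    gap: int = 12,
    seed: int = 0,
    include_snabi: bool = False,
    name: str | None = None,
) -> PlasmidSpec:
    """Generate a synthetic circular reporter plasmid.

    The backbone is random A/C/G/T sequence scrubbed of CG dinucleotides, so
    every CpG dyad on the plasmid is deliberately placed: the target dyad
    (inside FspI site 1, ``gap`` nucleotides 3' of the PAM on the cis strand),
    one dyad inside the non-target FspI site 2, optionally one inside a SnaBI
    site, and the remainder as isolated CG plants.  A SacI site (no internal
    CpG) is included for linearisation in digest assays.

    Parameters
    ----------
    length : plasmid size in bp (>= 200).
    n_nontarget_cpg : number of non-target CpG dyads (site-2/SnaBI dyads count
        towards this number).
    gap : nucleotides strictly between the last PAM base and the target C
        (must be >= 2 so FspI site 1 clears the PAM).
    seed : RNG seed; generation is deterministic given the seed.
    include_snabi : also embed a SnaBI site around one non-target CpG.

    Raises
    ------
    LayoutError if the requested elements cannot be placed in ``length`` bp.
    """
    if length < 200:
        raise ValueError("length must be >= 200 bp")
    if n_nontarget_cpg < 0:
        raise ValueError("n_nontarget_cpg must be >= 0")
    if not 0 <= gap <= 60:
        raise ValueError("gap must be in [0, 60]")
    if gap < 2:
        raise LayoutError(
            "gap < 2 puts FspI site 1 on top of the PAM; the target CpG "
            "cannot be embedded in an FspI site"
        )
    if include_snabi and n_nontarget_cpg < 2:
        raise LayoutError("SnaBI site requires at least 2 non-target CpGs")

    rng = np.random.default_rng(seed)
    arr = _BASES[rng.integers(0, 4, size=length)]
    _strip_cpg(arr, rng)
    _strip_motif(arr, _SACI)  # FspI/SnaBI contain CG and cannot survive the scrub

    reserved = np.zeros(length, dtype=bool)

    def reserve(start0: int, n: int, margin: int = 1) -> None:
        idx = (np.arange(start0 - margin, start0 + n + margin)) % length
        reserved[idx] = True

    def write_motif(motif: str, start0: int) -> None:
        m = encode(motif)
        idx = (start0 + np.arange(m.size)) % length
        arr[idx] = m
        # guard the junctions: C|G across a boundary would add a dyad
        left = (start0 - 1) % length
        right = (start0 + m.size) % length
        if arr[left] == _C and m[0] == _G:
            arr[left] = _T
        if m[-1] == _C and arr[right] == _G:
            arr[right] = _A

    def place(motif: str, desired0: int) -> int:
        """Write motif at the first unreserved window at/after desired0."""
        n = len(motif)
        for shift in range(length):
            s0 = (desired0 + shift) % length
            idx = (np.arange(s0 - 2, s0 + n + 2)) % length
            if not reserved[idx].any():
                write_motif(motif, s0)
                reserve(s0, n, margin=2)
                return s0
        raise LayoutError(f"no room to place motif {motif!r}")

    # protospacer + PAM (TGG keeps the PAM CpG-free)
    proto0 = min(100, length // 8)
    pam0 = proto0 + _PROTOSPACER_LEN
    reserve(proto0, _PROTOSPACER_LEN)
    write_motif("TGG", pam0)
    reserve(pam0, 3)
    pam_end0 = pam0 + 2

    # FspI site 1: its CpG C must land `gap` nt past the PAM
    target_c0 = pam_end0 + gap + 1
    site1_0 = target_c0 - 2
    if site1_0 <= pam_end0:
        raise LayoutError("FspI site 1 overlaps the PAM")
    write_motif(_FSPI, site1_0)
    reserve(site1_0, len(_FSPI))

    nontarget: list[int] = []
    sites: list[tuple[str, int, str]] = [("FspI", site1_0 + 1, "+")]

    sac0 = place(_SACI, int(round(0.25 * length)) % length)
    sites.append(("SacI", sac0 + 1, "+"))

    if n_nontarget_cpg >= 1:
        site2_0 = place(_FSPI, int(round(0.55 * length)) % length)
        sites.append(("FspI", site2_0 + 1, "+"))
        nontarget.append(site2_0 + 2)  # 0-based C of the embedded CpG
    if include_snabi:
        snabi0 = place(_SNABI, int(round(0.70 * length)) % length)
        sites.append(("SnaBI", snabi0 + 1, "+"))
        nontarget.append(snabi0 + 2)

    # plant the remaining isolated CG dyads (planting a CG next to non-C
    # bases cannot create a second dyad)
    remaining = n_nontarget_cpg - len(nontarget)
    free = np.flatnonzero(~reserved)
    # exclude the wrap position and positions whose neighbourhood is reserved
    ok = []
    for p0 in free:
        if p0 + 1 >= length:
            continue
        win = np.arange(p0 - 1, p0 + 3) % length
        if not reserved[win].any():
            ok.append(p0)
    ok_arr = np.array(ok, dtype=np.int64)
    rng.shuffle(ok_arr)
    taken = np.zeros(length, dtype=bool)
    planted = 0
    for p0 in ok_arr:
        if planted == remaining:
            break
        win = np.arange(p0 - 2, p0 + 4) % length
        if taken[win].any() or reserved[np.arange(p0 - 1, p0 + 3) % length].any():
            continue
        old = arr[[p0, p0 + 1]].copy()
        arr[p0] = _C
        arr[p0 + 1] = _G
        # a planted C/G may complete a stray restriction site with its flanks
        local = decode(arr[np.arange(p0 - 5, p0 + 7) % length])
        if _SACI in local or _FSPI in local or _SNABI in local:
            arr[[p0, p0 + 1]] = old
            continue
        taken[np.arange(p0 - 1, p0 + 3) % length] = True
        nontarget.append(int(p0))
        planted += 1
    if planted < remaining:
        raise LayoutError(
            f"could not place {remaining} non-target CpG dyads in {length} bp"
        )

    # break any unintended enzyme site completed by motif/PAM/plant flanks:
    # mutate one unprotected base inside the stray occurrence to A/T (which
    # can never create a CG dyad)
    protected = np.zeros(length, dtype=bool)
    protected[(proto0 + np.arange(_PROTOSPACER_LEN + 3)) % length] = True
    for _enz_name, start1, _strand in sites:
        protected[(start1 - 1 + np.arange(6)) % length] = True
    for p1 in nontarget:
        protected[[p1 % length, (p1 + 1) % length]] = True
    protected[[target_c0 % length, (target_c0 + 1) % length]] = True
    designed_starts = {(s[1] - 1) % length for s in sites}
    for _round in range(50):
        dirty = False
        doubled_seq = decode(arr) + decode(arr[:8])
        for motif in (_FSPI, _SACI, _SNABI):
            start = 0
            while True:
                i = doubled_seq.find(motif, start)
                if i == -1 or i >= length:
                    break
                if i % length not in designed_starts:
                    offs = [(i + o) % length for o in range(len(motif))]
                    free = [o for o, q in enumerate(offs) if not protected[q]]
                    if not free:
                        raise LayoutError("cannot repair stray restriction site")
                    o = free[0]
                    arr[offs[o]] = _T if motif[o] == "A" else _A
                    dirty = True
                start = i + 1
        if not dirty:
            break
    else:
        raise LayoutError("stray restriction site repair did not converge")

    sequence = decode(arr)
    expected = n_nontarget_cpg + 1
    got = count_cpg_dyads(sequence)
    if got != expected:
        raise LayoutError(f"layout check failed: {got} CpG dyads != {expected}")

    return PlasmidSpec(
        name=name or f"synthetic_reporter_g{gap}",
        sequence=sequence,
        protospacer_start=proto0 + 1,
        protospacer_strand="+",
        pam_end=pam_end0 + 1,
        target_cpg_pos=target_c0 + 1,
        gap=gap,
        nontarget_cpg_positions=tuple(sorted(p + 1 for p in nontarget)),
        restriction_sites=tuple(sites),
    )


# ---------------------------------------------------------------------------
# condition profiles

@dataclass(frozen=True)
class ConditionProfile:
    """Parametric ground-truth methylation frequency model for one condition.

    The per-strand frequency at gap g is a von-Mises-shaped angular factor
    (period ``period_T`` bp, sharpness ``kappa``) scaled by the strand
    amplitude, floored at ``baseline``, and windowed to ``support``.
    """

    condition_name: str
    linker_length: int
    period_T: float
    peak_gap: dict = field(default_factory=dict)        # {'cis': bp, 'trans': bp}
    amplitude: dict = field(default_factory=dict)       # {'cis': f, 'trans': f}
    kappa: float = 1.0
    support: tuple[int, int] = (8, 26)
    baseline: float = 0.006
    offtarget_median: float = 0.006
    offtarget_dispersion: float = 1.0

    def __post_init__(self):
        if self.period_T <= 0:
            raise ValueError("period_T must be > 0")
        if self.support[0] > self.support[1]:
            raise ValueError("support must satisfy g_min <= g_max")
        for s in ("cis", "trans"):
            if not 0.0 <= self.baseline <= self.amplitude[s] <= 1.0:
                raise ValueError("need 0 <= baseline <= amplitude <= 1")

    @property
    def optimal_gap(self) -> int:
        """Integer gap with the highest trans-strand frequency."""
        return int(round(self.peak_gap["trans"]))


def condition_profile(profile: ConditionProfile, gap: float, strand: str) -> float:
    """Ground-truth methylation frequency at a gap for one strand.

    Returns ``baseline`` outside the support window; inside, the amplitude-
    scaled angular factor clipped to [baseline, 1].
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if strand not in ("cis", "trans"):
        raise ValueError("strand must be 'cis' or 'trans'")
    g_min, g_max = profile.support
    if not g_min <= gap <= g_max:
        return profile.baseline
    peak = profile.peak_gap[strand]
    amp = profile.amplitude[strand]
    ang = math.cos(2.0 * math.pi * (gap - peak) / profile.period_T) - 1.0
    val = amp * math.exp(profile.kappa * ang)
    return min(1.0, max(profile.baseline, val))


def load_conditions() -> dict[str, ConditionProfile]:
    """Load the packaged condition profile table."""
    text = resources.files("methyltarget.data").joinpath("conditions.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for cname, d in raw.items():
        out[cname] = ConditionProfile(
            condition_name=cname,
            linker_length=int(d["linker_length"]),
            period_T=float(d["period_T"]),
            peak_gap={k: float(v) for k, v in d["peak_gap"].items()},
            amplitude={k: float(v) for k, v in d["amplitude"].items()},
            kappa=float(d["kappa"]),
            support=(int(d["support"][0]), int(d["support"][1])),
            baseline=float(d["baseline"]),
            offtarget_median=float(d["offtarget_median"]),
            offtarget_dispersion=float(d.get("offtarget_dispersion", 1.0)),
        )
    return out


def get_condition(name: str) -> ConditionProfile:
    conditions = load_conditions()
    try:
        return conditions[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; packaged: {sorted(conditions)}"
        ) from None


# ---------------------------------------------------------------------------
# off-target baseline

def sample_offtarget_frequencies(
    n_sites: int,
    median_freq: float,
    dispersion: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw 2*n_sites per-cytosine off-target frequencies from a Beta baseline.

    The Beta is parameterised as Beta(alpha=dispersion, beta) with beta solved
    numerically so the distribution's median equals ``median_freq``.  Larger
    dispersion concentrates draws around the median (the infinite-dispersion
    limit is a point mass at the median).
    """
    if not 0.0 < median_freq < 1.0:
        raise ValueError("median_freq must be in (0, 1)")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    a = float(dispersion)

    def median_gap(log_b: float) -> float:
        return stats.beta.ppf(0.5, a, math.exp(log_b)) - median_freq

    lo, hi = -20.0, 40.0
    if median_gap(lo) < 0 or median_gap(hi) > 0:
        raise ValueError(
            f"cannot parameterise Beta(median={median_freq}, dispersion={dispersion})"
        )
    b = math.exp(brentq(median_gap, lo, hi, xtol=1e-12))
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.beta(a, b, size=2 * n_sites)


# ---------------------------------------------------------------------------
# truth table

def make_truth(
    plasmid: PlasmidSpec,
    profile: ConditionProfile,
    seed: int = 0,
) -> "pd.DataFrame":
    """Ground-truth per-cytosine methylation frequencies for every CpG dyad.

    One row per cytosine (two per dyad).  The cis strand is the plus
    (protospacer/PAM) strand; the partner cytosine of a dyad at plus-position
    p sits at position p+1 on the minus strand.
    """
    import pandas as pd

    rows = []
    t = plasmid.target_cpg_pos
    rows.append((t, "+", condition_profile(profile, plasmid.gap, "cis"), True, "cis"))
    rows.append((t + 1, "-", condition_profile(profile, plasmid.gap, "trans"), True, "trans"))
    nt = plasmid.nontarget_cpg_positions
    if nt:
        freqs = sample_offtarget_frequencies(
            len(nt), profile.offtarget_median, profile.offtarget_dispersion, seed=seed
        )
        for i, p in enumerate(nt):
            rows.append((p, "+", float(freqs[2 * i]), False, "cis"))
            rows.append((p + 1, "-", float(freqs[2 * i + 1]), False, "trans"))
    df = pd.DataFrame(rows, columns=["pos", "strand", "freq", "target", "cis_trans"])
    return df.sort_values(["pos", "strand"], ignore_index=True)


# ---------------------------------------------------------------------------
# bisulfite read simulation

@dataclass
class ReadSet:
    """Directional bisulfite reads plus a per-read ground-truth sidecar.

    ``bases`` holds ascii-encoded read sequences (one row per read, all the
    same length).  ``origin_pos`` is the 1-based plus-strand start of the
    covered window regardless of origin strand; minus-origin reads are
    reported 5'->3' on the minus strand.  The sidecar arrays record, for every
    CpG-context cytosine of every source molecule, whether it was methylated.
    """

    bases: np.ndarray
    origin_pos: np.ndarray
    origin_strand: np.ndarray  # '+' / '-' per read
    sidecar_read: np.ndarray   # read index per sidecar entry
    sidecar_pos: np.ndarray    # 1-based cytosine position
    sidecar_strand: np.ndarray
    sidecar_meth: np.ndarray   # bool

    @property
    def n_reads(self) -> int:
        return self.bases.shape[0]

    @property
    def read_length(self) -> int:
        return self.bases.shape[1]

    def read_id(self, i: int) -> str:
        return f"r{i:07d}"

    def sequence(self, i: int) -> str:
        return decode(self.bases[i])

    def iter_records(self) -> Iterator[tuple[str, str]]:
        for i in range(self.n_reads):
            yield self.read_id(i), self.sequence(i)

    def to_fastq(self, path, quality_char: str = "I") -> None:
        q = quality_char * self.read_length
        with open(path, "w") as fh:
            for rid, seq in self.iter_records():
                fh.write(f"@{rid}\n{seq}\n+\n{q}\n")

    def sidecar_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "read_id": [self.read_id(i) for i in self.sidecar_read],
                "pos": self.sidecar_pos,
                "strand": self.sidecar_strand,
                "methylated": self.sidecar_meth.astype(int),
            }
        )

    def origin_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "read_id": [self.read_id(i) for i in range(self.n_reads)],
                "origin_pos": self.origin_pos,
                "origin_strand": self.origin_strand,
            }
        )


def _truth_arrays(plasmid: PlasmidSpec, truth) -> tuple[np.ndarray, np.ndarray]:
    """Per-position truth frequency lookup for each strand (0 elsewhere)."""
    L = plasmid.length
    tp = np.zeros(L)
    tm = np.zeros(L)
    for pos, strand, freq in zip(truth["pos"], truth["strand"], truth["freq"]):
        i = (int(pos) - 1) % L
        if strand == "+":
            tp[i] = freq
        else:
            tm[i] = freq
    return tp, tm


def _cpg_masks(plasmid: PlasmidSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of CpG-context cytosine positions on each strand."""
    arr = encode(plasmid.sequence)
    nxt = np.roll(arr, -1)
    prv = np.roll(arr, 1)
    cpg_plus = (arr == _C) & (nxt == _G)     # C of a plus-strand CG
    cpg_minus = (arr == _G) & (prv == _C)    # minus-strand C (plus G of a CG)
    return cpg_plus, cpg_minus


def simulate_bisulfite_reads(
    plasmid: PlasmidSpec,
    truth,
    coverage: float,
    read_length: int = 100,
    conversion_rate: float = 0.995,
    error_rate: float = 0.001,
    seed: int = 0,
    chunk_size: int = 50_000,
) -> ReadSet:
    """Simulate directional whole-plasmid bisulfite reads.

    Molecules are drawn uniformly from both strands of the circular plasmid.
    Each CpG cytosine of a molecule is methylated with its ground-truth
    frequency; methylated cytosines never convert, unmethylated cytosines (any
    context) convert C->T with probability ``conversion_rate``; independent
    substitution errors are applied at ``error_rate``.  Only the two original
    converted strands are sequenced (directional protocol).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    L = plasmid.length
    if read_length > L:
        raise ValueError("read_length must be <= plasmid length")
    for r, nm in ((conversion_rate, "conversion_rate"), (error_rate, "error_rate")):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{nm} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    tp, tm = _truth_arrays(plasmid, truth)
    cpg_plus, cpg_minus = _cpg_masks(plasmid)
    arr = encode(plasmid.sequence)
    doubled = np.concatenate([arr, arr])

    n_reads = max(1, int(round(coverage * L / read_length)))
    offs = np.arange(read_length)

    out_bases = np.empty((n_reads, read_length), dtype=np.uint8)
    origin_pos = np.empty(n_reads, dtype=np.int64)
    minus_flag = np.empty(n_reads, dtype=bool)
    sc_read, sc_pos, sc_strand, sc_meth = [], [], [], []

    for lo in range(0, n_reads, chunk_size):
        hi = min(lo + chunk_size, n_reads)
        m = hi - lo
        starts = rng.integers(0, L, size=m)
        is_minus = rng.random(m) < 0.5
        posmat = (starts[:, None] + offs) % L
        W = doubled[starts[:, None] + offs]  # plus-frame window

        truthmat = np.where(is_minus[:, None], tm[posmat], tp[posmat])
        meth = rng.random((m, read_length)) < truthmat
        conv = rng.random((m, read_length)) < conversion_rate

        plus_c = (W == _C) & ~is_minus[:, None]
        minus_c = (W == _G) & is_minus[:, None]

        out = W.copy()
        out[plus_c & ~meth & conv] = _T
        out[minus_c & ~meth & conv] = _A

        err = rng.random((m, read_length)) < error_rate
        if err.any():
            shift = rng.integers(1, 4, size=(m, read_length))
            idx = _BASE_IDX[out]
            out[err] = _BASES[(idx[err] + shift[err]) % 4]

        # minus-origin molecules are read 5'->3' on the minus strand
        if is_minus.any():
            rows = np.flatnonzero(is_minus)
            out[rows] = _COMP_LUT[out[rows][:, ::-1]]

        out_bases[lo:hi] = out
        origin_pos[lo:hi] = starts + 1
        minus_flag[lo:hi] = is_minus

        # sidecar: CpG-context cytosines of the source molecule
        cell = (plus_c & cpg_plus[posmat]) | (minus_c & cpg_minus[posmat])
        ri, ci = np.nonzero(cell)
        sc_read.append(ri + lo)
        sc_pos.append(posmat[ri, ci] + 1)
        sc_strand.append(np.where(is_minus[ri], "-", "+"))
        sc_meth.append(meth[ri, ci])

    return ReadSet(
        bases=out_bases,
        origin_pos=origin_pos,
        origin_strand=np.where(minus_flag, "-", "+"),
        sidecar_read=np.concatenate(sc_read) if sc_read else np.array([], dtype=int),
        sidecar_pos=np.concatenate(sc_pos) if sc_pos else np.array([], dtype=int),
        sidecar_strand=np.concatenate(sc_strand) if sc_strand else np.array([], dtype="U1"),
        sidecar_meth=np.concatenate(sc_meth) if sc_meth else np.array([], dtype=bool),
    )
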