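"""In-silico methylation-sensitive restriction-protection assay.

FspI and SnaBI carry a CpG inside their recognition sequence and are blocked
from cutting when that CpG is methylated; SacI has no internal CpG and always
cuts (used to linearise the circular plasmid).  Given per-site methylation
frequencies, this module predicts the restriction fragment patterns of the
molecular population: each methylation-blockable site cuts with a probability
derived from the methylation state of its blocking CpG, sites are assumed
independent, all 2^k cut subsets are enumerated exactly, and identical
fragment-length multisets are merged.  This is the in-silico counterpart of
a gel band pattern, at the fragment-length/molecular-fraction level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .simdata import PlasmidSpec, revcomp

__all__ = [
    "EnzymeDef",
    "DEFAULT_ENZYMES",
    "locate_sites",
    "cut_probability",
    "fragment_bands",
    "monte_carlo_bands",
    "MissingMethylationError",
    "TooManySitesError",
]


class MissingMethylationError(KeyError):
    """Methylation data absent for a blocking CpG."""


class TooManySitesError(ValueError):
    """Blocked-site count exceeds the exact enumeration bound."""


@dataclass(frozen=True)
class EnzymeDef:
    """A restriction enzyme with optional methylation blocking.

    ``cut_offset`` is the number of bases from the site start (top strand)
    to the cut; ``blocking_cpg_offset`` is the 0-based offset within the
    recognition sequence of the C (third base for FspI/SnaBI) of the CpG
    whose methylation blocks cleavage, or None for methylation-insensitive
    enzymes.
    """

    name: str
    recognition: str
    cut_offset: int
    blocking_cpg_offset: int | None = None

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise ValueError("recognition length must be >= 4")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the site")
        if self.blocking_cpg_offset is not None:
            off = self.blocking_cpg_offset
            if not 0 <= off < len(self.recognition) - 1:
                raise ValueError("blocking_cpg_offset must lie within the site")
            if self.recognition[off : off + 2] != "CG":
                raise ValueError("no CG at blocking_cpg_offset")


# standard REBASE facts: FspI TGC^GCA blunt, SacI GAGCT^C, SnaBI TAC^GTA blunt
DEFAULT_ENZYMES: dict[str, EnzymeDef] = {
    "FspI": EnzymeDef("FspI", "TGCGCA", cut_offset=3, blocking_cpg_offset=2),
    "SacI": EnzymeDef("SacI", "GAGCTC", cut_offset=5, blocking_cpg_offset=None),
    "SnaBI": EnzymeDef("SnaBI", "TACGTA", cut_offset=3, blocking_cpg_offset=2),
}


def locate_sites(sequence: str, enzyme: EnzymeDef) -> list[tuple[int, str]]:
    """All circular occurrences of the recognition sequence, 1-based starts.

    Palindromic sites are counted once (on the plus strand); for a
    non-palindromic recognition, minus-strand occurrences are reported with
    strand '-' at the plus-strand start of the covered window.
    """
    L = len(sequence)
    n = len(enzyme.recognition)
    doubled = sequence + sequence[: n - 1]
    hits = []
    motifs = [(enzyme.recognition, "+")]
    rc = revcomp(enzyme.recognition)
    if rc != enzyme.recognition:
        motifs.append((rc, "-"))
    for motif, strand in motifs:
        start = 0
        while True:
            i = doubled.find(motif, start)
            if i == -1 or i >= L:
                break
            hits.append((i + 1, strand))
            start = i + 1
    return sorted(set(hits))


def _blocking_freqs(site_start: int, enzyme: EnzymeDef, methylation: pd.DataFrame,
                    length: int) -> tuple[float, float]:
    """(plus, minus) methylation frequencies at a site's blocking CpG."""
    c_pos = (site_start - 1 + enzyme.blocking_cpg_offset) % length + 1
    g_pos = c_pos % length + 1
    freq_col = "freq" if "freq" in methylation.columns else None
    if freq_col is None:
        raise MissingMethylationError("methylation table lacks a 'freq' column")

    def lookup(pos, strand):
        rows = methylation[(methylation["pos"] == pos) & (methylation["strand"] == strand)]
        if rows.empty or rows[freq_col].isna().all():
            raise MissingMethylationError(
                f"no methylation data at pos {pos} strand {strand}"
            )
        return float(rows[freq_col].iloc[0])

    return lookup(c_pos, "+"), lookup(g_pos, "-")


def cut_probability(
    site_start: int,
    enzyme: EnzymeDef,
    methylation: pd.DataFrame,
    length: int,
    rule: str = "either",
) -> float:
    """Probability that a molecule is cut at a site, under a blocking rule.

    'either': methylation on either strand blocks -> cut = (1-p1)(1-p2);
    'both': both strands must be methylated to block -> cut = 1 - p1*p2;
    'none': methylation never blocks -> cut = 1.
    """
    if rule not in ("either", "both", "none"):
        raise ValueError("rule must be 'either', 'both' or 'none'")
    if rule == "none" or enzyme.blocking_cpg_offset is None:
        return 1.0
    p1, p2 = _blocking_freqs(site_start, enzyme, methylation, length)
    if rule == "either":
        return (1.0 - p1) * (1.0 - p2)
    return 1.0 - p1 * p2


def _site_table(
    plasmid: PlasmidSpec,
    enzymes: list[EnzymeDef],
    methylation: pd.DataFrame | None,
    rule: str,
) -> list[dict]:
    sites = []
    for enz in enzymes:
        for start, strand in locate_sites(plasmid.sequence, enz):
            cut0 = (start - 1 + enz.cut_offset) % plasmid.length
            if enz.blocking_cpg_offset is None or rule == "none":
                p_cut = 1.0
            else:
                p_cut = cut_probability(start, enz, methylation, plasmid.length, rule)
            sites.append(
                dict(enzyme=enz.name, start=start, strand=strand,
                     cut_coord=cut0, p_cut=p_cut)
            )
    return sites


def _fragments(cut_coords: list[int], length: int) -> tuple[int, ...]:
    if not cut_coords:
        return (length,)
    cuts = np.sort(np.unique(cut_coords))
    if cuts.size == 1:
        return (length,)
    diffs = np.diff(cuts)
    wrap = length - (cuts[-1] - cuts[0])
    return tuple(sorted([int(x) for x in diffs] + [int(wrap)], reverse=True))


def fragment_bands(
    plasmid: PlasmidSpec,
    enzymes: list[EnzymeDef],
    methylation: pd.DataFrame | None = None,
    rule: str = "either",
    max_enumeration: int = 20,
) -> pd.DataFrame:
    """Predicted restriction band pattern of the molecular population.

    Enumerates every cut subset of methylation-blockable sites (unblockable
    sites always cut), weights each subset by its product probability under
    site independence, computes circular fragment lengths, and merges
    identical length multisets.  Fractions sum to 1 and fragment lengths in
    every pattern sum to the plasmid length.
    """
    sites = _site_table(plasmid, enzymes, methylation, rule)
    always = [s for s in sites if s["p_cut"] == 1.0]
    variable = [s for s in sites if s["p_cut"] < 1.0]
    if len(variable) > max_enumeration:
        raise TooManySitesError(
            f"{len(variable)} blockable sites exceed the enumeration bound "
            f"({max_enumeration}); use monte_carlo_bands"
        )
    base_cuts = [s["cut_coord"] for s in always]
    acc: dict[tuple[int, ...], float] = {}
    for states in product((False, True), repeat=len(variable)):
        prob = 1.0
        cuts = list(base_cuts)
        for cut, s in zip(states, variable):
            prob *= s["p_cut"] if cut else (1.0 - s["p_cut"])
            if cut:
                cuts.append(s["cut_coord"])
        if prob == 0.0:
            continue
        frag = _fragments(cuts, plasmid.length)
        acc[frag] = acc.get(frag, 0.0) + prob
    rows = sorted(acc.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "pattern_id": range(len(rows)),
            "fragments": [r[0] for r in rows],
            "n_fragments": [len(r[0]) for r in rows],
            "fraction": [r[1] for r in rows],
        }
    )


def monte_carlo_bands(
    plasmid: PlasmidSpec,
    enzymes: list[EnzymeDef],
    methylation: pd.DataFrame | None = None,
    rule: str = "either",
    n_molecules: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-molecule sampling counterpart of ``fragment_bands``.

    Samples the cut state of each blockable site independently per molecule;
    used as an independent cross-check of the exact enumeration.
    """
    rng = np.random.default_rng(seed)
    sites = _site_table(plasmid, enzymes, methylation, rule)
    always = [s["cut_coord"] for s in sites if s["p_cut"] == 1.0]
    variable = [s for s in sites if s["p_cut"] < 1.0]
    counts: dict[tuple[int, ...], int] = {}
    if variable:
        draws = rng.random((n_molecules, len(variable))) < np.array(
            [s["p_cut"] for s in variable]
        )
    else:
        draws = np.zeros((n_molecules, 0), dtype=bool)
    for i in range(n_molecules):
        cuts = list(always) + [
            s["cut_coord"] for s, c in zip(variable, draws[i]) if c
        ]
        frag = _fragments(cuts, plasmid.length)
        counts[frag] = counts.get(frag, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "pattern_id": range(len(rows)),
            "fragments": [r[0] for r in rows],
            "n_fragments": [len(r[0]) for r in rows],
            "fraction": [r[1] / n_molecules for r in rows],
        }
    )
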