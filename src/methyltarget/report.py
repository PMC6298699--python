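"""Summary statistics, condition comparisons and pipeline orchestration.

Statistics mirror how targeted-methylation experiments are summarised:
median off-target frequency over all non-target CpG cytosines, Pearson (or
Spearman) replicate correlation of per-site off-target frequencies, and
Welch two-sample t (unpaired) or Wilcoxon signed-rank (paired) condition
comparisons.  P values are raw per-comparison values; no multiple-testing
correction is applied.

``run_pipeline`` wires the whole analysis together: build the synthetic
plasmid, draw ground-truth methylation for the chosen condition, simulate
directional bisulfite reads, align and call methylation, compute the gap
profile summaries and the restriction band prediction, and emit a
deterministic machine-readable summary.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import bsquant, digest, geometry, simdata

__all__ = [
    "ComparisonResult",
    "median_offtarget",
    "replicate_correlation",
    "compare_conditions",
    "run_pipeline",
    "PipelineError",
    "DEFAULT_CONFIG",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    test: str


def _freq_column(table: pd.DataFrame, corrected: bool = False) -> pd.Series:
    if corrected and "freq_corrected" in table.columns:
        return table["freq_corrected"]
    return table["freq"]


def median_offtarget(table: pd.DataFrame, corrected: bool = False) -> float:
    """Median estimated frequency over all non-target CpG cytosines."""
    sub = table[~table["target"].astype(bool)]
    vals = _freq_column(sub, corrected).dropna()
    if vals.empty:
        raise ValueError("no covered non-target cytosines")
    return float(vals.median())


def replicate_correlation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    method: str = "pearson",
    corrected: bool = False,
) -> float:
    """Correlation of paired non-target frequencies between two replicates."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    ka = a[~a["target"].astype(bool)].set_index(["pos", "strand"])
    kb = b[~b["target"].astype(bool)].set_index(["pos", "strand"])
    fa = _freq_column(ka, corrected)
    fb = _freq_column(kb, corrected)
    joined = pd.concat([fa.rename("a"), fb.rename("b")], axis=1, join="outer")
    joined = joined.dropna()
    if joined.empty:
        raise ValueError("replicates share no covered non-target sites")
    only_a = fa.dropna().index.difference(kb.index)
    only_b = fb.dropna().index.difference(ka.index)
    if len(only_a) or len(only_b):
        raise ValueError("replicate tables cover different site sets")
    if method == "pearson":
        r, _ = stats.pearsonr(joined["a"], joined["b"])
    else:
        r, _ = stats.spearmanr(joined["a"], joined["b"])
    return float(r)


def compare_conditions(x, y, paired: bool = False) -> ComparisonResult:
    """Compare replicate frequency measurements between two conditions.

    Unpaired: Welch two-sample t-test (group variances are not assumed
    equal).  Paired: Wilcoxon signed-rank test on the differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired comparison needs equal-length groups")
        if x.size < 2:
            raise ValueError("need >= 2 pairs")
        res = stats.wilcoxon(x, y, method="exact" if x.size <= 25 else "auto")
        return ComparisonResult(
            statistic=float(res.statistic),
            degrees_of_freedom=float("nan"),
            p_value=float(res.pvalue),
            mean_x=float(x.mean()), mean_y=float(y.mean()),
            sd_x=float(x.std(ddof=1)), sd_y=float(y.std(ddof=1)),
            test="wilcoxon_signed_rank",
        )
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        equal = x.mean() == y.mean()
        return ComparisonResult(
            statistic=0.0 if equal else float("inf"),
            degrees_of_freedom=float(x.size + y.size - 2),
            p_value=1.0 if equal else 0.0,
            mean_x=float(x.mean()), mean_y=float(y.mean()),
            sd_x=0.0, sd_y=0.0,
            test="welch_t",
        )
    t, p = stats.ttest_ind(x, y, equal_var=False)
    se2 = vx / x.size + vy / y.size
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    return ComparisonResult(
        statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=float(p),
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)), sd_y=float(y.std(ddof=1)),
        test="welch_t",
    )


# ---------------------------------------------------------------------------
# pipeline

DEFAULT_CONFIG: dict = {
    "condition": "linker15",
    "gap": 12,
    "length": 4000,
    "n_nontarget_cpg": 241,
    "coverage": 1000.0,
    "read_length": 100,
    "conversion_rate": 0.995,
    "error_rate": 0.001,
    "seed": 1,
    "min_coverage": 10,
    "max_mismatch": None,
    "correct_conversion": False,
    "enzymes": ["FspI", "SacI"],
    "digest_rule": "either",
    "support_threshold": 0.02,
    "profile_gaps": [2, 42],
    "include_snabi": False,
}


def _log(msg: str, quiet: bool) -> None:
    if not quiet:
        print(f"[methyltarget] {msg}", file=sys.stderr)


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def run_pipeline(config: dict | None = None, outdir=None, quiet: bool = False) -> dict:
    """Run the full synthetic analysis; deterministic given the master seed.

    Returns a bundle with the summary dict and every intermediate table.
    Stage seeds are derived from the master seed by fixed offsets.  When
    ``correct_conversion`` is true, summary frequencies are background-
    corrected for incomplete bisulfite conversion.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    master = int(cfg["seed"])

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as e:  # noqa: BLE001 - stage identification
            raise PipelineError(f"stage {name!r} failed: {e}") from e
        _log(f"{name}: {time.perf_counter() - t0:.2f}s", quiet)
        return out

    profile = stage("profile", lambda: simdata.get_condition(cfg["condition"]))
    plasmid = stage(
        "simulate-plasmid",
        lambda: simdata.build_plasmid(
            length=int(cfg["length"]),
            n_nontarget_cpg=int(cfg["n_nontarget_cpg"]),
            gap=int(cfg["gap"]),
            seed=simdata.derive_seed(master, 1),
            include_snabi=bool(cfg["include_snabi"]),
        ),
    )
    truth = stage(
        "truth", lambda: simdata.make_truth(plasmid, profile, seed=simdata.derive_seed(master, 2))
    )
    reads = stage(
        "simulate-reads",
        lambda: simdata.simulate_bisulfite_reads(
            plasmid,
            truth,
            coverage=float(cfg["coverage"]),
            read_length=int(cfg["read_length"]),
            conversion_rate=float(cfg["conversion_rate"]),
            error_rate=float(cfg["error_rate"]),
            seed=simdata.derive_seed(master, 3),
        ),
    )
    report, site_table = stage(
        "quantify",
        lambda: bsquant.quantify_reads(
            reads,
            plasmid,
            max_mismatch=cfg["max_mismatch"],
            min_coverage=int(cfg["min_coverage"]),
        ),
    )
    background = None
    if cfg["correct_conversion"]:
        # self-calibrating background: apparent methylation at non-CpG
        # cytosines (none is real in this system) estimates non-conversion
        # plus sequencing error without trusting the configured rate
        background = stage("background", lambda: bsquant.estimated_background(report))
        table = bsquant.estimate_frequencies(
            report, int(cfg["min_coverage"]), conversion_rate=1.0 - background
        )
        table = bsquant.label_cis_trans(table, plasmid)
        site_table = table[table["context"] == "CpG"].reset_index(drop=True)
    g0, g1 = cfg["profile_gaps"]
    series = stage("profile-series", lambda: geometry.profile_series(profile, range(int(g0), int(g1) + 1)))
    period = stage("period", lambda: geometry.dominant_period(series))
    support = stage(
        "support", lambda: geometry.methylation_support(series, float(cfg["support_threshold"]))
    )
    enzymes = [digest.DEFAULT_ENZYMES[e] for e in cfg["enzymes"]]
    bands = stage(
        "digest",
        lambda: digest.fragment_bands(
            plasmid, enzymes, methylation=truth, rule=cfg["digest_rule"]
        ),
    )

    use_corr = bool(cfg["correct_conversion"])
    tgt = site_table[site_table["target"]]
    tgt_cis = tgt[tgt["cis_trans"] == "cis"]
    tgt_trans = tgt[tgt["cis_trans"] == "trans"]

    def one(sub):
        vals = _freq_column(sub, use_corr).dropna()
        return float(vals.iloc[0]) if len(vals) else float("nan")

    truth_cis = simdata.condition_profile(profile, plasmid.gap, "cis")
    truth_trans = simdata.condition_profile(profile, plasmid.gap, "trans")

    summary = {
        "condition": cfg["condition"],
        "gap": plasmid.gap,
        "plasmid_length": plasmid.length,
        "n_cpg_dyads": simdata.count_cpg_dyads(plasmid.sequence),
        "n_nontarget_cpg": len(plasmid.nontarget_cpg_positions),
        "coverage": float(cfg["coverage"]),
        "n_reads": reads.n_reads,
        "conversion_rate": float(cfg["conversion_rate"]),
        "corrected": use_corr,
        "estimated_background": background,
        "target_cis_freq": one(tgt_cis),
        "target_trans_freq": one(tgt_trans),
        "target_cis_truth": truth_cis,
        "target_trans_truth": truth_trans,
        "offtarget_median": median_offtarget(site_table, corrected=use_corr),
        "offtarget_median_raw": median_offtarget(site_table, corrected=False),
        "offtarget_median_truth": profile.offtarget_median,
        "dominant_period_bp": period,
        "support_g_min": None if support is None else support[0],
        "support_g_max": None if support is None else support[1],
        "n_band_patterns": len(bands),
        "seed": master,
    }

    bundle = {
        "summary": summary,
        "plasmid": plasmid,
        "truth": truth,
        "reads": reads,
        "report": report,
        "site_table": site_table,
        "profile_series": series,
        "bands": bands,
    }

    if outdir is not None:
        from pathlib import Path

        from . import io as mio

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_plasmid(plasmid, out / "plasmid.fasta", out / "plasmid.json")
        mio.write_tsv(truth, out / "truth.tsv")
        mio.write_tsv(report, out / "cx_report.tsv")
        mio.write_tsv(site_table, out / "site_table.tsv")
        mio.write_tsv(series, out / "gap_profile.tsv")
        bands_out = bands.copy()
        bands_out["fragments"] = bands_out["fragments"].map(
            lambda t: ",".join(str(x) for x in t)
        )
        mio.write_tsv(bands_out, out / "bands.tsv")
        with open(out / "summary.txt", "w") as fh:
            for k in sorted(summary):
                fh.write(f"{k}\t{_fmt(summary[k])}\n")
    return bundle
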