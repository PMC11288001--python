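"""Read recruitment, RPKM abundance matrices, and environmental statistics.

Recruitment maps virome reads against a dereplicated reference set through a
k-mer index; a read is counted (once) for its best reference when the
alignment clears >= 95% nucleotide identity, >= 50 aligned bases, and >= 80%
of the read aligned — equal-best ties go to the lexicographically smallest
reference id so reruns are reproducible.  Abundance is normalized as RPKM
with the per-sample denominator being the total of *recruited* reads (the
comparison is within the family-specific reference set); the raw library
size can be supplied instead.

Environmental analysis reports, per genome and covariate, Pearson r,
Spearman rho, the OLS slope, and a two-sided p (exact permutation p when
n <= 8), plus a Benjamini-Hochberg column; the high-vs-low G+C contrast is
a two-sided Mann-Whitney U test (exact for small tie-free groups, else the
tie-corrected normal approximation).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import NtIndex
from .seqio import GenomeRecord


class BiogeoError(ValueError):
    pass


@dataclass
class AbundanceMatrix:
    rpkm: pd.DataFrame            # genomes x samples
    counts: pd.DataFrame          # raw recruited counts
    totals: pd.Series             # per-sample denominator (mapped reads)
    lengths: pd.Series            # per-genome length (bp)


def recruit_reads(reads_by_sample: dict[str, list[tuple[str, str]]],
                  refs: list[GenomeRecord], id_min: float = 0.95,
                  aln_min: int = 50, readcov_min: float = 0.80,
                  k: int = 15, probe_step: int = 7) -> pd.DataFrame:
    """Per-genome read counts for each sample (genomes x samples).

    Each read is mapped through the reference k-mer index; the best segment
    is kept if identity >= id_min AND aligned length >= aln_min AND aligned
    fraction of the read >= readcov_min.  Ties on score go to the smallest
    reference id; a read counts at most once.
    """
    if not refs:
        raise BiogeoError("empty reference set")
    index = NtIndex(refs, k=k)
    samples = sorted(reads_by_sample)
    counts = pd.DataFrame(0, index=[r.id for r in refs], columns=samples)
    for sample in samples:
        for _name, seq in reads_by_sample[sample]:
            segs = index.map_segments(seq, probe_step=probe_step)
            best = None
            for s in segs:
                if (s.identity >= id_min and s.aligned_cols >= aln_min
                        and s.aligned_cols / len(seq) >= readcov_min):
                    best = s
                    break  # segments sorted by score then subject id
            if best is not None:
                counts.loc[best.subject_id, sample] += 1
    return counts


def rpkm(counts: pd.DataFrame, lengths: dict[str, int] | pd.Series,
         totals: pd.Series | None = None) -> AbundanceMatrix:
    """RPKM[g,s] = count / ((len_g/1e3) * (total_s/1e6)).

    ``totals`` defaults to the per-sample recruited totals (column sums).
    A sample with zero total yields a zero column with a warning.
    """
    lengths = pd.Series(lengths).astype(float)
    missing = set(counts.index) - set(lengths.index)
    if missing:
        raise BiogeoError(f"no length for genomes: {sorted(missing)}")
    if (lengths.loc[list(counts.index)] <= 0).any():
        raise BiogeoError("zero-length genome")
    if totals is None:
        totals = counts.sum(axis=0).astype(float)
    else:
        totals = pd.Series(totals).astype(float)
    out = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    for s in counts.columns:
        t = totals[s]
        if t == 0:
            warnings.warn(f"sample {s}: zero mapped reads; RPKM column is 0")
            continue
        out[s] = counts[s] / (lengths.loc[counts.index] / 1e3) / (t / 1e6)
    return AbundanceMatrix(rpkm=out, counts=counts, totals=totals,
                           lengths=lengths.loc[counts.index])


def _perm_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for the Pearson correlation."""
    obs = abs(_pearson(x, y))
    n = 0
    hits = 0
    for perm in itertools.permutations(y):
        n += 1
        if abs(_pearson(x, np.array(perm))) >= obs - 1e-12:
            hits += 1
    return hits / n


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    den = math.sqrt((xs ** 2).sum() * (ys ** 2).sum())
    return float((xs * ys).sum() / den) if den > 0 else 0.0


def env_correlate(abund: AbundanceMatrix, meta: pd.DataFrame,
                  variables: tuple = ("latitude", "temperature", "salinity"),
                  ) -> pd.DataFrame:
    """Per-genome correlation/regression of RPKM against covariates.

    Columns: genome, variable, n, r, rho, slope, p, p_bh, note.  p is the
    two-sided t-distribution p for r (exact permutation p when n <= 8);
    zero-variance genomes get NA with a note.  Benjamini-Hochberg is applied
    per variable across genomes.
    """
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    rows = []
    for var in variables:
        if var not in meta.columns:
            continue
        joined = meta.loc[abund.rpkm.columns, var].astype(float)
        ok = ~joined.isna()
        x = joined[ok].to_numpy()
        if ok.sum() < 3:
            raise BiogeoError(f"{var}: fewer than 3 samples with data")
        if np.allclose(x.std(), 0.0):
            for genome in abund.rpkm.index:
                rows.append({"genome": genome, "variable": var,
                             "n": int(ok.sum()), "r": np.nan, "rho": np.nan,
                             "slope": np.nan, "p": np.nan,
                             "note": "zero-variance covariate"})
            continue
        for genome in abund.rpkm.index:
            y = abund.rpkm.loc[genome, ok.index[ok]].to_numpy(dtype=float)
            if np.allclose(y.std(), 0.0):
                rows.append({"genome": genome, "variable": var,
                             "n": int(ok.sum()), "r": np.nan, "rho": np.nan,
                             "slope": np.nan, "p": np.nan,
                             "note": "zero-variance abundance"})
                continue
            r, p_t = stats.pearsonr(x, y)
            rho = stats.spearmanr(x, y).statistic
            slope = stats.linregress(x, y).slope
            p = _perm_pvalue(x, y) if len(x) <= 8 else p_t
            rows.append({"genome": genome, "variable": var,
                         "n": int(ok.sum()), "r": float(r), "rho": float(rho),
                         "slope": float(slope), "p": float(p), "note": ""})
    df = pd.DataFrame(rows, columns=["genome", "variable", "n", "r", "rho",
                                     "slope", "p", "note"])
    df["p_bh"] = np.nan
    for var in df.variable.unique():
        m = (df.variable == var) & df.p.notna()
        df.loc[m, "p_bh"] = _benjamini_hochberg(df.loc[m, "p"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def mannwhitney_exact_or_asymptotic(x: np.ndarray, y: np.ndarray
                                    ) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U of x vs y.

    Exact null distribution when both groups have <= 8 observations and no
    cross-group ties; otherwise the tie-corrected normal approximation.
    Returns (U of x, p, method).
    """
    ties = len(set(x) & set(y)) > 0
    if len(x) <= 8 and len(y) <= 8 and not ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue), "asymptotic"


def group_compare(abund: AbundanceMatrix, gc_values: dict[str, float],
                  split: float = 0.45) -> dict:
    """High- vs low-G+C genome abundance contrast (Mann-Whitney U).

    Genomes are pooled by mean RPKM into G+C > split vs < split (a genome
    exactly at the split joins the higher group).  Returns a report dict
    with group sizes, medians, U, p, and the direction of the difference.
    """
    means = abund.rpkm.mean(axis=1)
    low = [g for g in means.index if gc_values[g] < split]
    high = [g for g in means.index if gc_values[g] >= split]
    if not low or not high:
        raise BiogeoError("both G+C groups must be non-empty")
    x = means.loc[low].to_numpy()
    y = means.loc[high].to_numpy()
    u, p, method = mannwhitney_exact_or_asymptotic(x, y)
    return {
        "n_low_gc": len(low), "n_high_gc": len(high),
        "median_low_gc": float(np.median(x)),
        "median_high_gc": float(np.median(y)),
        "U": u, "p": p, "method": method,
        "direction": ("low>high" if np.median(x) > np.median(y)
                      else "high>low" if np.median(y) > np.median(x)
                      else "none"),
        "split": split,
    }


def abundance_long_table(abund: AbundanceMatrix, meta: pd.DataFrame,
                         gc_values: dict[str, float] | None = None,
                         ) -> pd.DataFrame:
    """Long-format RPKM table joined to sample metadata (heatmap-ready)."""
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    rows = []
    for genome in abund.rpkm.index:
        for sample in abund.rpkm.columns:
            row = {"genome": genome, "sample": sample,
                   "rpkm": float(abund.rpkm.loc[genome, sample])}
            for col in meta.columns:
                row[col] = meta.loc[sample, col]
            if gc_values is not None:
                row["gc"] = gc_values[genome]
            rows.append(row)
    return pd.DataFrame(rows)


def plot_heatmap(abund: AbundanceMatrix, path,
                 gc_values: dict[str, float] | None = None,
                 gc_split: float = 0.45) -> None:
    """Genomes x samples RPKM heatmap, rows annotated by G+C class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = abund.rpkm
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * data.shape[1]), max(3, 0.3 * data.shape[0])))
    im = ax.imshow(np.log1p(data.to_numpy()), aspect="auto", cmap="viridis")
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=6)
    labels = list(data.index)
    if gc_values is not None:
        labels = [f"{g} ({'high' if gc_values[g] >= gc_split else 'low'} GC)"
                  for g in labels]
    ax.set_yticks(range(data.shape[0]), labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="log1p(RPKM)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
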