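"""Quantitative genetics of phyllotaxy deviations.

Covers: per-plant summary metrics of the deviation series, interquartile
outlier screening, broad-sense heritability from a one-way random-effects
model (H = sigma_G^2 / (sigma_G^2 + sigma_R^2 / n) with n the minimum
replicate number), marker quality control, Bonferroni-type significance
thresholds from an effective marker count, a single-marker linear scan, and
a resampling association procedure that repeatedly masks a fraction of
phenotype records and reports per-marker resampling model inclusion
probabilities (RMIP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

Array = np.ndarray

__all__ = [
    "GenotypeMatrix", "QcResult", "HeritabilityModel", "AssociationConfig",
    "RmipTable", "summary_metrics", "SUMMARY_METRICS", "iqr_outlier_flag",
    "heritability", "marker_qc", "bonferroni_threshold", "iteration_threshold",
    "scan", "rmip", "ld_r2", "read_vcf", "write_vcf",
]


# ---------------------------------------------------------------------------
# genotype container and VCF I/O


@dataclass
class GenotypeMatrix:
    """Markers-by-individuals dosage matrix (0/1/2, NaN for missing calls)."""

    dosages: Array
    chrom: Array
    pos: Array
    ids: Array
    ref: Array
    alt: Array                 # comma-joined alternate alleles
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be markers x individuals")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (np.any(finite < 0) or np.any(finite > 2)):
            raise ValueError("dosages must lie in {0, 1, 2} or be missing")

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def is_biallelic(self) -> Array:
        return np.array(["," not in a for a in self.alt])

    def is_indel(self) -> Array:
        def indel(ref, alt):
            return len(ref) != 1 or any(len(a) != 1 for a in alt.split(","))
        return np.array([indel(r, a) for r, a in zip(self.ref, self.alt)])

    def missing_fraction(self) -> Array:
        return np.mean(~np.isfinite(self.dosages), axis=1)

    def het_fraction(self) -> Array:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages == 1, axis=1)

    def maf(self) -> Array:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosages, axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(self, marker_mask: Array | None = None,
               samples: list[str] | None = None) -> "GenotypeMatrix":
        d = self.dosages
        chrom, pos, ids, ref, alt = self.chrom, self.pos, self.ids, self.ref, self.alt
        smp = list(self.samples)
        if marker_mask is not None:
            marker_mask = np.asarray(marker_mask)
            d = d[marker_mask]
            chrom, pos, ids = chrom[marker_mask], pos[marker_mask], ids[marker_mask]
            ref, alt = ref[marker_mask], alt[marker_mask]
        if samples is not None:
            idx = [smp.index(s) for s in samples]
            d = d[:, idx]
            smp = list(samples)
        return GenotypeMatrix(dosages=d.copy(), chrom=chrom.copy(), pos=pos.copy(),
                              ids=ids.copy(), ref=ref.copy(), alt=alt.copy(),
                              samples=smp)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read dosages from a VCF; multi-allelic sites keep their full ALT list
    so quality control can drop them, with dosage counted for the first
    alternate allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, chrom, pos, ids, ref, alt = [], [], [], [], [], []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        ref.append(var.REF)
        alt.append(",".join(var.ALT) if var.ALT else ".")
    return GenotypeMatrix(dosages=np.array(rows) if rows else np.empty((0, len(samples))),
                          chrom=np.array(chrom), pos=np.array(pos, dtype=int),
                          ids=np.array(ids), ref=np.array(ref), alt=np.array(alt),
                          samples=samples)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal diploid GT-only VCF (text, uncompressed)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted(set(gm.chrom.tolist()))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for m in range(gm.n_markers):
            calls = [code.get(d, "./.") if np.isfinite(d) else "./."
                     for d in gm.dosages[m]]
            fh.write("\t".join([str(gm.chrom[m]), str(int(gm.pos[m])), str(gm.ids[m]),
                                str(gm.ref[m]), str(gm.alt[m]), ".", "PASS", ".",
                                "GT"] + calls) + "\n")


# ---------------------------------------------------------------------------
# phenotype summaries


def _metric_median_all(df):
    return df["value"].median()


def _metric_mean_all(df):
    return df["value"].mean()


def _metric_max_all(df):
    return df["value"].max()


def _metric_min_all(df):
    return df["value"].min()


def _per_angle(stat, i):
    def f(df):
        sub = df.loc[df["angle_index"] == i, "value"]
        return getattr(sub, stat)() if len(sub) else np.nan
    return f


def _per_timepoint_median(t):
    def f(df):
        sub = df.loc[df["timepoint"] == t, "value"]
        return sub.median() if len(sub) else np.nan
    return f


#: configurable summary menu; the headline metric is the per-plant median of
#: the lower-four deviations pooled over all timepoints
SUMMARY_METRICS = {
    "median_all": _metric_median_all,
    "mean_all": _metric_mean_all,
    "max_all": _metric_max_all,
    "min_all": _metric_min_all,
    **{f"angle{i}_median": _per_angle("median", i) for i in range(1, 5)},
    **{f"angle{i}_mean": _per_angle("mean", i) for i in range(1, 5)},
    **{f"timepoint{t}_median": _per_timepoint_median(t) for t in range(1, 4)},
}


def summary_metrics(table: pd.DataFrame,
                    metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-plant summaries of the deviation series.

    ``table`` must have columns plant_id, genotype_id, timepoint,
    angle_index (1-based from the bottom of the canopy) and value (the
    deviation Phi in degrees).  Returns one row per plant with one column per
    selected metric.
    """
    metrics = list(SUMMARY_METRICS) if metrics is None else list(metrics)
    if not metrics:
        raise ValueError("empty metric selection")
    unknown = [m for m in metrics if m not in SUMMARY_METRICS]
    if unknown:
        raise KeyError(f"unknown metrics: {unknown}")
    rows = []
    for (plant, geno), df in table.groupby(["plant_id", "genotype_id"], sort=True):
        row = {"plant_id": plant, "genotype_id": geno}
        for m in metrics:
            row[m] = SUMMARY_METRICS[m](df)
        rows.append(row)
    return pd.DataFrame(rows)


def iqr_outlier_flag(values: Array, k: float = 1.5) -> Array:
    """Tukey fence flags: outside ``[Q1 - k IQR, Q3 + k IQR]``."""
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least four values for quartile screening")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v > q3 + k * iqr) | (v < q1 - k * iqr)


# ---------------------------------------------------------------------------
# heritability


@dataclass(frozen=True)
class HeritabilityModel:
    """Fitted one-way random-effects model Y = mu + delta_i + eps_ij."""

    mu: float
    sigma2_g: float
    sigma2_r: float
    n: int
    n_genotypes: int
    n_records: int
    method: str

    @property
    def H(self) -> float:
        denom = self.sigma2_g + self.sigma2_r / self.n
        if denom <= 0:
            return 0.0
        return float(np.clip(self.sigma2_g / denom, 0.0, 1.0))


def _anova_components(values: Array, groups: Array) -> tuple[float, float, float]:
    """Method-of-moments (Henderson) variance components, truncated at zero.

    For balanced designs these coincide with the restricted-likelihood
    estimates whenever the genotypic component is interior.
    """
    df_all = pd.DataFrame({"y": values, "g": groups})
    k = df_all["g"].nunique()
    n_tot = len(df_all)
    if k < 2:
        raise ValueError("need at least two genotypes")
    counts = df_all.groupby("g")["y"].count()
    if (counts > 1).sum() == 0:
        raise ValueError("all genotypes unreplicated: genotypic variance is "
                         "not identifiable")
    means = df_all.groupby("g")["y"].transform("mean")
    ssw = float(((df_all["y"] - means) ** 2).sum())
    sigma_r = ssw / max(n_tot - k, 1)
    grand = df_all["y"].mean()
    gmeans = df_all.groupby("g")["y"].mean()
    ssb = float((counts * (gmeans - grand) ** 2).sum())
    msb = ssb / (k - 1)
    n0 = (n_tot - float((counts ** 2).sum()) / n_tot) / (k - 1)
    sigma_g = max((msb - sigma_r) / n0, 0.0)
    return float(grand), sigma_g, float(sigma_r)


def _reml_components(values: Array, groups: Array) -> tuple[float, float, float]:
    import statsmodels.api as sm

    df_all = pd.DataFrame({"y": values, "g": groups})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df_all["y"], np.ones((len(df_all), 1)), groups=df_all["g"])
        fit = model.fit(reml=True)
    sigma_g = float(np.clip(fit.cov_re.iloc[0, 0], 0.0, None))
    sigma_r = float(fit.scale)
    return float(fit.params.iloc[0]), sigma_g, sigma_r


def heritability(table: pd.DataFrame, value_col: str = "value",
                 genotype_col: str = "genotype_id", n: int = 2,
                 method: str = "auto", max_reps: int | None = None,
                 seed: int = 0) -> HeritabilityModel:
    """Broad-sense heritability from genotype-replicated phenotypes.

    ``n`` is the replication divisor applied to the residual variance
    (default 2, the minimum replicate number in a partially replicated
    panel).  ``max_reps`` optionally caps each genotype's contribution to a
    seeded random subsample, so a heavily replicated check genotype does not
    dominate the variance components.

    method: ``"auto"`` uses the closed-form estimator for balanced designs
    and restricted maximum likelihood otherwise; ``"mom"`` and ``"reml"``
    force the estimator.
    """
    df = table[[genotype_col, value_col]].dropna().copy()
    if max_reps is not None:
        rng = np.random.default_rng(seed)
        parts = []
        for _, sub in df.groupby(genotype_col, sort=True):
            if len(sub) > max_reps:
                sub = sub.iloc[np.sort(rng.choice(len(sub), max_reps, replace=False))]
            parts.append(sub)
        df = pd.concat(parts, ignore_index=True)
    values = df[value_col].to_numpy(dtype=float)
    groups = df[genotype_col].to_numpy()
    counts = pd.Series(groups).value_counts()
    balanced = counts.nunique() == 1
    if method == "auto":
        method_used = "anova-reml" if balanced else "reml"
    else:
        method_used = method
    if method_used in ("mom", "anova-reml"):
        mu, sg, sr = _anova_components(values, groups)
    elif method_used == "reml":
        _anova_components(values, groups)  # validates identifiability
        try:
            mu, sg, sr = _reml_components(values, groups)
        except Exception:
            mu, sg, sr = _anova_components(values, groups)
            method_used = "mom-fallback"
    else:
        raise ValueError(f"unknown method {method!r}")
    return HeritabilityModel(mu=mu, sigma2_g=sg, sigma2_r=sr, n=n,
                             n_genotypes=int(counts.size), n_records=len(values),
                             method=method_used)


# ---------------------------------------------------------------------------
# marker quality control and thresholds


@dataclass
class QcResult:
    filtered: GenotypeMatrix
    kept: Array
    exclusion_counts: dict[str, int]


def marker_qc(gm: GenotypeMatrix, max_missing: float = 0.30,
              max_het: float = 0.10, min_maf: float = 0.05) -> QcResult:
    """Keep biallelic SNPs with missingness < 30%, heterozygosity < 10% and
    minor allele frequency >= 5%.

    Missingness is computed over all individuals; heterozygosity and MAF over
    non-missing calls.  The filters are independent predicates, so applying
    them in any order yields the same marker set.
    """
    biallelic = gm.is_biallelic()
    snp = ~gm.is_indel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        miss_ok = gm.missing_fraction() < max_missing
        het = gm.het_fraction()
        maf = gm.maf()
    het_ok = np.where(np.isfinite(het), het < max_het, False)
    maf_ok = np.where(np.isfinite(maf), maf >= min_maf, False)
    kept = biallelic & snp & miss_ok & het_ok & maf_ok
    counts = {
        "not_biallelic": int((~biallelic).sum()),
        "indel": int((~snp).sum()),
        "missingness": int((~miss_ok).sum()),
        "heterozygosity": int((~het_ok).sum()),
        "maf": int((~maf_ok).sum()),
    }
    if kept.sum() == 0:
        warnings.warn("no markers survive quality control", stacklevel=2)
    return QcResult(filtered=gm.subset(marker_mask=kept), kept=kept,
                    exclusion_counts=counts)


def bonferroni_threshold(alpha: float, me: float) -> float:
    """Family-wise threshold alpha / Me over the effective marker count."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if me <= 0:
        raise ValueError("effective marker count must be positive")
    return alpha / me


def iteration_threshold(alpha: float, me: float, m: float) -> float:
    """Model-selection entry threshold alpha / (Me / M) for iterative scan
    engines that iterate on the ratio of effective to total markers."""
    if not (0 < me <= m):
        raise ValueError("require 0 < Me <= M")
    return alpha * m / me


# ---------------------------------------------------------------------------
# association scan and resampling inclusion probabilities


def scan(dosages: Array, phenotype: Array, covariates: Array | None = None) -> Array:
    """Two-sided p-values from a per-marker linear regression on dosage.

    Missing dosages are dropped marker-by-marker.  With covariates the
    phenotype and dosage are residualized per marker (ordinary least squares)
    and the test degrees of freedom reduced accordingly.  A constant
    phenotype yields p = 1 everywhere with a warning.
    """
    x = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(y):
        raise ValueError("dosages must be markers x samples matching phenotype")
    if np.nanstd(y) == 0:
        warnings.warn("constant phenotype: association is undefined", stacklevel=2)
        return np.ones(x.shape[0])
    if covariates is None:
        return _scan_marginal(x, y)
    cov = np.column_stack([np.ones(len(y)), np.atleast_2d(covariates).reshape(len(y), -1)])
    pvals = np.ones(x.shape[0])
    for m in range(x.shape[0]):
        ok = np.isfinite(x[m]) & np.isfinite(y)
        n_ok = int(ok.sum())
        dfree = n_ok - 2 - (cov.shape[1] - 1)
        if n_ok < 3 or dfree < 1 or np.std(x[m, ok]) == 0:
            continue
        c = cov[ok]
        ry = y[ok] - c @ np.linalg.lstsq(c, y[ok], rcond=None)[0]
        rx = x[m, ok] - c @ np.linalg.lstsq(c, x[m, ok], rcond=None)[0]
        if np.std(rx) == 0 or np.std(ry) == 0:
            continue
        r = float(np.corrcoef(rx, ry)[0, 1])
        pvals[m] = _r_to_p(r, dfree)
    return pvals


def _scan_marginal(x: Array, y: Array) -> Array:
    ok = np.isfinite(x) & np.isfinite(y)[None, :]
    n = ok.sum(axis=1).astype(float)
    xs = np.where(ok, x, 0.0)
    ys = np.where(ok, y[None, :], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = xs.sum(axis=1) / n
        my = ys.sum(axis=1) / n
        sxy = (xs * ys).sum(axis=1) - n * mx * my
        sxx = (xs ** 2).sum(axis=1) - n * mx ** 2
        syy = (ys ** 2).sum(axis=1) - n * my ** 2
        r = sxy / np.sqrt(sxx * syy)
    pvals = np.ones(x.shape[0])
    dfree = n - 2
    valid = np.isfinite(r) & (dfree >= 1) & (n >= 3)
    r = np.clip(r[valid], -1.0, 1.0)
    d = dfree[valid]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(d / np.maximum(1.0 - r ** 2, 1e-300))
    pvals[valid] = 2.0 * stats.t.sf(np.abs(t), d)
    return pvals


def _r_to_p(r: float, dfree: int) -> float:
    r = float(np.clip(r, -1.0, 1.0))
    if 1.0 - r ** 2 <= 0:
        return 0.0
    t = abs(r) * np.sqrt(dfree / (1.0 - r ** 2))
    return float(2.0 * stats.t.sf(t, dfree))


@dataclass(frozen=True)
class AssociationConfig:
    """Configuration of the resampling association procedure."""

    alpha: float = 0.05
    me: float = 1.0                # effective (independent) marker count
    m: float | None = None         # total marker count; defaults to me
    n_iter: int = 100
    mask_frac: float = 0.10
    rmip_call: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mask_frac < 1):
            raise ValueError("mask_frac must lie in (0, 1)")
        total = self.m if self.m is not None else self.me
        if self.me > total:
            raise ValueError("effective markers cannot exceed total markers")
        if self.n_iter < 1:
            raise ValueError("n_iter must be positive")

    @property
    def p_threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.me)


@dataclass
class RmipTable:
    """Per-marker resampling model inclusion probabilities."""

    table: pd.DataFrame            # chrom, pos, id, hits, rmip, called
    config: AssociationConfig

    def called(self, threshold: float | None = None) -> pd.DataFrame:
        thr = self.config.rmip_call if threshold is None else threshold
        return self.table[self.table["rmip"] >= thr].reset_index(drop=True)


def rmip(gm: GenotypeMatrix, phenotype: Array, cfg: AssociationConfig,
         engine=scan, covariates: Array | None = None) -> RmipTable:
    """Resampling inclusion probabilities: repeatedly mask a fraction of
    phenotype records, rescan, and count significance exceedances per marker.

    RMIP = exceedances / iterations, so every value is an exact multiple of
    ``1 / n_iter``.  Markers at or above ``cfg.rmip_call`` are flagged as
    called; a stricter or looser reporting threshold can be applied via
    :meth:`RmipTable.called`.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != gm.n_samples:
        raise ValueError("phenotype length must match sample count")
    n_mask = int(round(cfg.mask_frac * len(y)))
    if len(y) - n_mask < 10:
        raise ValueError("masking leaves fewer than 10 phenotype records")
    rng = np.random.default_rng(cfg.seed)
    thr = cfg.p_threshold
    hits = np.zeros(gm.n_markers, dtype=int)
    for _ in range(cfg.n_iter):
        masked = rng.choice(len(y), size=n_mask, replace=False)
        keep = np.ones(len(y), dtype=bool)
        keep[masked] = False
        cov = covariates[keep] if covariates is not None else None
        pvals = engine(gm.dosages[:, keep], y[keep], cov) if cov is not None \
            else engine(gm.dosages[:, keep], y[keep])
        hits += pvals < thr
    table = pd.DataFrame({
        "chrom": gm.chrom, "pos": gm.pos, "id": gm.ids,
        "hits": hits, "rmip": hits / cfg.n_iter,
    })
    table["called"] = table["rmip"] >= cfg.rmip_call
    return RmipTable(table=table, config=cfg)


def ld_r2(gm: GenotypeMatrix, i: int, j: int) -> float:
    """Squared dosage correlation between two markers over shared non-missing
    individuals; NaN when fewer than three are shared or a marker is
    monomorphic among them."""
    a = gm.dosages[i]
    b = gm.dosages[j]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan")
    a, b = a[ok], b[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)
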