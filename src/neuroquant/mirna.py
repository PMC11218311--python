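"""Plasma miRNA differential-expression screen.

Implements the statistics of a small-cohort case/control miRNA-seq screen:
expression filtering (count >= 10 in more than half the samples of each
group), TMM library normalization, a negative-binomial conditional exact
test with a method-of-moments common dispersion, Benjamini–Hochberg FDR,
DEM selection at |log2FC| > 1 and FDR < 0.05, a 95%-interval signature rule
applied to individual case samples, PCA of normalized expression, and
2^-ΔΔCt relative expression for qPCR validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CASE = "case"
CONTROL = "control"


# ---------------------------------------------------------------- containers


@dataclass
class CountMatrix:
    """Feature × sample count matrix with case/control labels.

    ``counts``: DataFrame, rows = feature ids (unique), columns = sample ids.
    ``sample_groups``: Series indexed by sample id with values
    "case"/"control".
    """

    counts: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = [
            s for s in self.counts.columns if s not in self.sample_groups.index
        ]
        if missing:
            raise ValueError(f"unlabeled samples: {missing}")
        bad = set(self.sample_groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.sample_groups = self.sample_groups.loc[self.counts.columns]

    @property
    def case_samples(self) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == CONTROL])

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors (geometric mean 1)."""

    factors: pd.Series
    effective_library_sizes: pd.Series = field(default=None)  # type: ignore


def read_counts_tsv(counts_path, samples_path) -> CountMatrix:
    """Read a feature × sample TSV plus a (sample_id, group) sample sheet."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    groups = pd.Series(
        sheet.iloc[:, 1].to_numpy(), index=sheet.iloc[:, 0].to_numpy()
    )
    return CountMatrix(counts, groups)


# ----------------------------------------------------------------- filtering


def filter_by_expression(
    m: CountMatrix, min_count: int = 10, min_frac: float = 0.5
) -> CountMatrix:
    """Keep features expressed (count >= min_count) in strictly more than
    ``min_frac`` of the samples of *each* group. Order is preserved."""
    keep = np.ones(len(m.counts), dtype=bool)
    for samples in (m.case_samples, m.control_samples):
        if not samples:
            raise ValueError("both groups must be nonempty")
        expressed = (m.counts[samples] >= min_count).sum(axis=1)
        keep &= (expressed > min_frac * len(samples)).to_numpy()
    if not keep.any():
        warnings.warn("expression filter removed every feature")
    return CountMatrix(m.counts.loc[keep], m.sample_groups)


# ------------------------------------------------------------------- TMM


def _quantile_depth(counts: np.ndarray, lib: np.ndarray, q: float) -> np.ndarray:
    return np.array(
        [np.quantile(counts[:, j] / lib[j], q) for j in range(counts.shape[1])]
    )


def tmm_normalize(
    m: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample vs a reference (the sample whose upper-quartile
    depth-normalized count is closest to the mean), the log2 ratios M of
    depth-normalized counts are doubly trimmed — 30% on M, 5% on the average
    abundance A — and averaged with inverse-variance (delta-method) weights.
    Factors are rescaled to geometric mean 1.
    """
    counts = m.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs positive total counts")
    f75 = _quantile_depth(counts, lib, 0.75)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(counts.shape[1])
    xr, nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        xj, nj = counts[:, j], lib[j]
        ok = (xj > 0) & (xr > 0)
        if not ok.any():
            warnings.warn(
                f"sample {m.counts.columns[j]} shares no expressed features "
                "with the reference; factor set to 1"
            )
            continue
        pj, pr = xj[ok] / nj, xr[ok] / nr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (nj - xj[ok]) / (nj * xj[ok]) + (nr - xr[ok]) / (nr * xr[ok])
        n = len(M)
        loM = np.floor(n * trim_m) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * trim_a) + 1
        hiA = n + 1 - loA
        rM = stats.rankdata(M, method="ordinal")
        rA = stats.rankdata(A, method="ordinal")
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if not keep.any() or w[keep].sum() <= 0:
            continue
        log_factors[j] = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])

    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    factors = pd.Series(factors, index=m.counts.columns)
    eff = pd.Series(lib, index=m.counts.columns) * factors
    return NormFactors(factors=factors, effective_library_sizes=eff)


def cpm(
    m: CountMatrix, nf: NormFactors | None = None, prior_count: float = 0.5
) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes (pseudo-count
    added before scaling so log-fold-changes are finite)."""
    lib = m.library_sizes.astype(float)
    if nf is not None:
        lib = lib * nf.factors
    return (m.counts + prior_count).div(lib, axis=1) * 1e6


def tpm(m: CountMatrix, nf: NormFactors | None = None) -> pd.DataFrame:
    """Transcripts per million. Mature miRNAs are of essentially equal
    length, so no length term enters and TPM coincides with CPM; emitted
    separately because reporting conventions differ."""
    return cpm(m, nf, prior_count=0.0)


# ------------------------------------------------------- dispersion and test


def estimate_common_dispersion(
    m: CountMatrix, nf: NormFactors | None = None
) -> float:
    """Method-of-moments common NB dispersion.

    Counts are scaled to a common effective depth; for each feature the
    within-group pooled variance v and mean mu give phi = (v - mu) / mu^2;
    the common value is the median over features with positive mean,
    clipped at 0.
    """
    lib = m.library_sizes.astype(float)
    if nf is not None:
        lib = lib * nf.factors
    scale = np.exp(np.mean(np.log(lib)))
    y = m.counts.div(lib, axis=1) * scale
    phis = []
    groups = [m.case_samples, m.control_samples]
    for _, row in y.iterrows():
        mus, resid, dof = [], 0.0, 0
        for g in groups:
            v = row[g].to_numpy()
            mus.append(v.mean())
            resid += ((v - v.mean()) ** 2).sum()
            dof += len(v) - 1
        mu = np.mean(mus)
        if mu <= 0 or dof <= 0:
            continue
        var = resid / dof
        phis.append((var - mu) / mu**2)
    if not phis:
        return 0.0
    return float(max(0.0, np.median(phis)))


def _nb_exact_p(
    s_case: float, s_ctrl: float, n_case: int, n_ctrl: int, dispersion: float
) -> float:
    """Two-sided conditional exact p-value for equality of NB means.

    The group sums are NB with common per-sample mean; conditional on the
    total, the case sum has a known distribution whose probabilities are
    summed over all outcomes no more likely than the observed one.  With
    dispersion 0 the conditional law is Binomial(total, n_case/n).
    """
    s_case, s_ctrl = int(round(s_case)), int(round(s_ctrl))
    s = s_case + s_ctrl
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if dispersion <= 1e-10:
        logp = stats.binom.logpmf(k, s, n_case / (n_case + n_ctrl))
    else:
        mu = s / (n_case + n_ctrl)
        size_a = n_case / dispersion
        size_b = n_ctrl / dispersion
        mu_a, mu_b = n_case * mu, n_ctrl * mu
        pa = size_a / (size_a + mu_a)
        pb = size_b / (size_b + mu_b)
        logp = stats.nbinom.logpmf(k, size_a, pa) + stats.nbinom.logpmf(
            s - k, size_b, pb
        )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[s_case]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def de_test(
    m: CountMatrix,
    nf: NormFactors | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-feature case-vs-control NB conditional exact test.

    Returns a DataFrame (feature_id, log2fc, p_value).  log2FC is the log2
    ratio of TMM-CPM group means with pseudo-count 0.5.  Counts are scaled
    to a common effective depth before summing within groups so that the
    conditional test sees depth-comparable sums.
    """
    if nf is None:
        nf = tmm_normalize(m)
    if dispersion is None:
        dispersion = estimate_common_dispersion(m, nf)
    lib = m.library_sizes.astype(float) * nf.factors
    scale = np.exp(np.mean(np.log(lib)))
    pseudo = m.counts.div(lib, axis=1) * scale

    expr = cpm(m, nf)
    case_s, ctrl_s = m.case_samples, m.control_samples
    lfc = np.log2(expr[case_s].mean(axis=1) / expr[ctrl_s].mean(axis=1))

    pvals = np.empty(len(m.counts))
    raw = m.counts.to_numpy()
    for i, (fid, row) in enumerate(pseudo.iterrows()):
        if raw[i].sum() == 0:
            pvals[i] = 1.0
            continue
        pvals[i] = _nb_exact_p(
            row[case_s].sum(), row[ctrl_s].sum(), len(case_s), len(ctrl_s),
            dispersion,
        )
    out = pd.DataFrame(
        {
            "feature_id": m.counts.index,
            "log2fc": np.where(raw.sum(axis=1) == 0, 0.0, lfc.to_numpy()),
            "p_value": pvals,
        }
    ).reset_index(drop=True)
    out.attrs["dispersion"] = dispersion
    out.attrs["test"] = "NB conditional exact (common dispersion, MoM)"
    return out


# ------------------------------------------------------------ FDR and DEMs


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def select_dems(
    records: pd.DataFrame, log2fc_cut: float = 1.0, fdr_cut: float = 0.05
) -> pd.DataFrame:
    """Assign up/down/ns status from |log2FC| and BH-FDR cutoffs."""
    out = records.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    sig = (out["fdr"] < fdr_cut) & (out["log2fc"].abs() > log2fc_cut)
    out["status"] = "ns"
    out.loc[sig & (out["log2fc"] > 0), "status"] = "up"
    out.loc[sig & (out["log2fc"] < 0), "status"] = "down"
    return out


# ----------------------------------------------------------- signature rule


def ci_signature(
    expression: pd.DataFrame,
    sample_groups: pd.Series,
    conf: float = 0.95,
    interval: str = "prediction",
    detect_threshold: float = 0.0,
) -> pd.DataFrame:
    """Flag features whose level in *every* case sample falls outside the
    95% interval of the control levels.

    ``interval`` = "prediction" (default): mean ± t · sd · sqrt(1 + 1/n),
    appropriate when the rule is applied to individual samples;
    "mean": mean ± t · sd / sqrt(n).  ``exclusive_to_cases`` marks features
    detected (> ``detect_threshold``) in at least one case and no control.
    """
    groups = sample_groups.loc[expression.columns]
    case_cols = groups.index[groups == CASE]
    ctrl_cols = groups.index[groups == CONTROL]
    n = len(ctrl_cols)
    if n < 3:
        raise ValueError("signature rule needs at least 3 controls")
    if interval not in ("prediction", "mean"):
        raise ValueError(f"unknown interval type: {interval}")
    tq = stats.t.ppf(0.5 + conf / 2, n - 1)
    widen = np.sqrt(1 + 1 / n) if interval == "prediction" else np.sqrt(1 / n)

    rows = []
    for fid, row in expression.iterrows():
        ctrl = row[ctrl_cols].to_numpy(dtype=float)
        case = row[case_cols].to_numpy(dtype=float)
        mu, sd = ctrl.mean(), ctrl.std(ddof=1)
        half = tq * sd * widen
        lo, hi = mu - half, mu + half
        outside = int(np.sum((case < lo) | (case > hi)))
        rows.append(
            {
                "feature_id": fid,
                "ci_lo": lo,
                "ci_hi": hi,
                "n_cases_outside": outside,
                "flagged": outside == len(case),
                "exclusive_to_cases": bool(
                    (case > detect_threshold).any()
                    and not (ctrl > detect_threshold).any()
                ),
                "degenerate_ci": sd == 0.0,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- PCA


def pca_scores(
    expression: pd.DataFrame, n_components: int | None = None,
    scale: bool = False,
) -> pd.DataFrame:
    """Sample scores of a centered (optionally scaled) PCA via SVD.

    Rows of ``expression`` are features, columns samples.  Sign convention:
    each component is flipped so its largest-magnitude feature loading is
    positive.  The explained-variance ratios are stored in
    ``result.attrs["explained_variance_ratio"]``.
    """
    X = expression.to_numpy(dtype=float).T  # samples × features
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if not np.any(Xc):
        raise ValueError("constant matrix: no variance to decompose")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC positive
    for k in range(len(S)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    if n_components is None:
        n_components = len(S)
    scores = U[:, :n_components] * S[:n_components]
    out = pd.DataFrame(
        scores,
        index=expression.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    var = S**2
    out.attrs["explained_variance_ratio"] = var / var.sum()
    return out


# -------------------------------------------------------------------- qPCR


def ddct_relative_expression(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ΔΔCt method."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
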