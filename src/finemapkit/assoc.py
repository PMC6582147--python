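"""Single-trait mixed-model association scans and multi-trait chi-square tests.

The per-marker model is y = mu + x b + g + e with g ~ N(0, sigma_g^2 G) and
e ~ N(0, sigma_e^2 R), R diagonal from phenotype reliabilities.  The variance
ratio sigma_g^2/sigma_e^2 is re-optimised for every marker by exact profile
REML on a one-time eigendecomposition of the reliability-scaled relationship
matrix (a GEMMA-style exact scan); an EMMAX-style fixed-ratio mode is
available for speed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.cluster import hierarchy

from .io import GenotypeSet
from .model_core import reliability_to_weight

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypePanel",
    "ScanResult",
    "QtlRegion",
    "qc_filter",
    "hwe_pvalues",
    "compute_grm",
    "single_marker_scan",
    "genomic_control",
    "trait_correlation",
    "multi_trait_chisq",
    "cluster_traits",
    "detect_peaks",
]


@dataclasses.dataclass
class PhenotypePanel:
    """Per-individual trait values (deregressed proofs) with reliabilities."""

    trait_values: pd.DataFrame
    reliabilities: pd.DataFrame

    def __post_init__(self):
        if not self.trait_values.index.equals(self.reliabilities.index) or list(
            self.trait_values.columns
        ) != list(self.reliabilities.columns):
            raise ValueError("trait_values and reliabilities must be aligned")
        present = self.trait_values.notna()
        if (present & self.reliabilities.isna()).any().any():
            raise ValueError("reliability missing for an observed trait value")
        bad = self.reliabilities[present]
        if ((bad <= 0) | (bad > 1)).any().any():
            raise ValueError("reliabilities must lie in (0, 1]")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.trait_values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.trait_values.columns)

    def n_observed(self, trait: str) -> int:
        return int(self.trait_values[trait].notna().sum())

    def observed(self, trait: str):
        """(individual ids, values, reliabilities) where the trait is recorded."""
        mask = self.trait_values[trait].notna()
        ids = list(self.trait_values.index[mask])
        return (
            ids,
            self.trait_values.loc[mask, trait].to_numpy(float),
            self.reliabilities.loc[mask, trait].to_numpy(float),
        )

    @classmethod
    def from_long_tsv(cls, path) -> "PhenotypePanel":
        df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
        required = {"individual_id", "trait", "value", "reliability"}
        if not required.issubset(df.columns):
            raise ValueError(f"phenotype TSV needs columns {sorted(required)}")
        values = df.pivot(index="individual_id", columns="trait", values="value")
        reliab = df.pivot(index="individual_id", columns="trait", values="reliability")
        return cls(values, reliab.loc[values.index, values.columns])

    def to_long_tsv(self, path) -> None:
        rows = []
        for trait in self.trait_names:
            mask = self.trait_values[trait].notna()
            rows.append(
                pd.DataFrame(
                    {
                        "individual_id": self.trait_values.index[mask],
                        "trait": trait,
                        "value": self.trait_values.loc[mask, trait],
                        "reliability": self.reliabilities.loc[mask, trait],
                    }
                )
            )
        pd.concat(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclasses.dataclass
class ScanResult:
    """Per-variant association results for one trait."""

    table: pd.DataFrame  # variant, chrom, pos, maf, beta, se, t, p
    trait: str
    lambda_gc: float = np.nan
    n_used: int = 0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path, trait: str) -> "ScanResult":
        tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        res = cls(table=tab, trait=trait)
        if len(tab) >= 100:
            res.lambda_gc = genomic_control(tab["p"].to_numpy())
        return res


@dataclasses.dataclass
class QtlRegion:
    chrom: str
    start: int
    end: int
    lead_variant: str
    lead_pos: int
    lead_p: float
    traits: list[str]
    source: str = "single-trait"
    n_significant: int = 0

    def __post_init__(self):
        if not self.start <= self.lead_pos <= self.end:
            raise ValueError("lead position outside region")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_pvalues(genotypes: GenotypeSet) -> np.ndarray:
    """Hardy-Weinberg chi-square (1 df) p-values on hard-called genotypes."""
    hard = np.rint(np.clip(genotypes.dosages, 0, 2)).astype(int)
    n = hard.shape[1]
    n2 = (hard == 2).sum(axis=1)
    n1 = (hard == 1).sum(axis=1)
    p = (2 * n2 + n1) / (2 * n)
    q = 1 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.stack([q**2, 2 * p * q, p**2], axis=1) * n
        obs = np.stack([n - n1 - n2, n1, n2], axis=1)
        chi2 = np.nansum(
            np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0), axis=1
        )
    pvals = stats.chi2.sf(chi2, df=1)
    pvals[(p == 0) | (p == 1)] = 1.0  # monomorphic: nothing to test
    return pvals


def qc_filter(
    genotypes: GenotypeSet,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
    return_report: bool = False,
):
    """Drop variants with MAF < maf_min or HWE p < hwe_alpha.

    HWE uses hard calls (fractional imputed dosages rounded for the test
    only).  Returns the filtered set, plus a per-criterion removal report
    when requested.  An empty result is a warning, not an error.
    """
    maf = genotypes.compute_maf()
    hwe_p = hwe_pvalues(genotypes)
    pass_maf = maf >= maf_min
    pass_hwe = hwe_p >= hwe_alpha
    keep = pass_maf & pass_hwe
    report = {
        "n_input": genotypes.n_variants,
        "n_removed_maf": int((~pass_maf).sum()),
        "n_removed_hwe": int((pass_maf & ~pass_hwe).sum()),
        "n_retained": int(keep.sum()),
    }
    logger.info("qc_filter: %s", report)
    if report["n_retained"] == 0:
        warnings.warn("no variants pass QC", stacklevel=2)
    out = genotypes.take(np.flatnonzero(keep))
    return (out, report) if return_report else out


def compute_grm(genotypes: GenotypeSet, maf_min: float = 0.01) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G = W'W / (2 sum p(1-p)) with W the allele-frequency-centred dosages;
    the mean diagonal is ~1 under Hardy-Weinberg equilibrium.
    """
    maf = genotypes.compute_maf()
    use = (maf >= maf_min) & (genotypes.dosages.std(axis=1) > 0)
    if not use.any():
        raise ValueError("no polymorphic variants for GRM")
    X = genotypes.dosages[use]
    p = X.mean(axis=1) / 2.0
    W = X - 2.0 * p[:, None]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    return (W.T @ W) / denom


# ---------------------------------------------------------------------------
# Single-marker mixed-model scan
# ---------------------------------------------------------------------------

def _marker_reml_grid(eta_grid, s, i_r, y_r):
    """Precompute grid weights and intercept/response pieces shared by markers."""
    Wg = 1.0 / (eta_grid[:, None] * s[None, :] + 1.0)  # (g, n)
    logdet_v = np.sum(np.log1p(eta_grid[:, None] * s[None, :]), axis=1)
    a11 = Wg @ (i_r * i_r)
    b1 = Wg @ (i_r * y_r)
    yy = Wg @ (y_r * y_r)
    return Wg, logdet_v, a11, b1, yy


def _marker_reml_at(eta, s, i_r, x_r, y_r):
    """Profile restricted log-likelihood for one marker at one eta."""
    w = 1.0 / (eta * s + 1.0)
    a11 = float(w @ (i_r * i_r))
    a12 = float(w @ (i_r * x_r))
    a22 = float(w @ (x_r * x_r))
    b1 = float(w @ (i_r * y_r))
    b2 = float(w @ (x_r * y_r))
    yy = float(w @ (y_r * y_r))
    det = a11 * a22 - a12 * a12
    if det <= 0:
        return -np.inf, None
    beta2 = (a11 * b2 - a12 * b1) / det
    beta1 = (b1 - a12 * beta2) / a11
    rss = yy - beta1 * b1 - beta2 * b2
    n = len(s)
    if rss <= 0:
        return -np.inf, None
    ll = -0.5 * (
        float(np.sum(np.log1p(eta * s))) + math.log(det) + (n - 2) * math.log(rss)
    )
    return ll, (beta2, det, a11, rss)


def single_marker_scan(
    panel: PhenotypePanel,
    trait: str,
    genotypes: GenotypeSet,
    grm: np.ndarray | None = None,
    use_reliability: bool = True,
    per_marker_vc: bool = True,
    grid_size: int = 32,
    min_samples: int = 30,
) -> ScanResult:
    """Mixed-model association scan of every variant against one trait.

    With ``per_marker_vc`` the variance ratio is re-optimised for each marker
    (grid + golden-section refinement on the exact restricted likelihood);
    otherwise the null-model ratio is reused for all markers.  With no GRM
    the scan is weighted least squares (exact OLS when R = I).
    """
    ids, y, r2 = panel.observed(trait)
    if len(ids) < min_samples:
        raise ValueError(f"trait {trait!r} has {len(ids)} records < {min_samples}")
    gsub = genotypes.select_individuals(ids)
    n = len(ids)
    weights = reliability_to_weight(r2) if use_reliability else np.ones(n)
    rsqi = 1.0 / np.sqrt(weights)

    if grm is None:
        s = np.zeros(n)
        U = None
        i_r = rsqi.copy()
        y_r = rsqi * y
        eta_grid = np.array([0.0])
    else:
        K = rsqi[:, None] * grm * rsqi[None, :]
        s, Uv = linalg.eigh(0.5 * (K + K.T))
        s = np.clip(s, 0.0, None)
        U = Uv
        i_r = U.T @ rsqi
        y_r = U.T @ (rsqi * y)
        eta_grid = np.concatenate([[0.0], np.geomspace(1e-4, 1e4, grid_size)])

    if grm is not None and not per_marker_vc:
        # EMMAX-style: optimise once on the null model, then fix
        from .model_core import fit_null_reml

        null = fit_null_reml(y, np.ones((n, 1)), grm, weights)
        eta_grid = np.array([null["eta"]])

    Wg, logdet_v, a11g, b1g, yyg = _marker_reml_grid(eta_grid, s, i_r, y_r)

    X_all = gsub.dosages * rsqi[None, :]  # (m, n) reliability-scaled
    if U is not None:
        X_all = X_all @ U  # rotate into the eigenbasis

    m = gsub.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tval = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    n_grid = len(eta_grid)

    for j in range(m):
        x_r = X_all[j]
        xx = Wg @ (x_r * x_r)
        xi = Wg @ (i_r * x_r)
        xy = Wg @ (x_r * y_r)
        det = a11g * xx - xi * xi
        ok = det > 0
        if not ok.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            b2 = (a11g * xy - xi * b1g) / det
            b1 = (b1g - xi * b2) / a11g
            rss = yyg - b1 * b1g - b2 * xy
            ll = -0.5 * (logdet_v + np.log(det) + (n - 2) * np.log(rss))
        ll[~ok | (rss <= 0)] = -np.inf
        k = int(np.argmax(ll))
        eta_hat = eta_grid[k]
        best = (b2[k], det[k], a11g[k], rss[k])
        if n_grid > 1 and per_marker_vc:
            lo = eta_grid[max(k - 1, 0)]
            hi = eta_grid[min(k + 1, n_grid - 1)]
            if hi > lo:
                invphi = (math.sqrt(5) - 1) / 2
                a, b = lo, hi
                x1 = b - invphi * (b - a)
                x2 = a + invphi * (b - a)
                f1, r1 = _marker_reml_at(x1, s, i_r, x_r, y_r)
                f2, r2_ = _marker_reml_at(x2, s, i_r, x_r, y_r)
                for _ in range(25):
                    if f1 < f2:
                        a, x1, f1, r1 = x1, x2, f2, r2_
                        x2 = a + invphi * (b - a)
                        f2, r2_ = _marker_reml_at(x2, s, i_r, x_r, y_r)
                    else:
                        b, x2, f2, r2_ = x2, x1, f1, r1
                        x1 = b - invphi * (b - a)
                        f1, r1 = _marker_reml_at(x1, s, i_r, x_r, y_r)
                fbest, rbest = (f1, r1) if f1 >= f2 else (f2, r2_)
                if rbest is not None and fbest > ll[k]:
                    best = rbest
        b2_hat, det_hat, a11_hat, rss_hat = best
        sigma2 = rss_hat / (n - 2)
        var_b = sigma2 * a11_hat / det_hat
        if var_b <= 0:
            continue
        beta[j] = b2_hat
        se[j] = math.sqrt(var_b)
        tval[j] = b2_hat / se[j]
        pval[j] = 2.0 * stats.t.sf(abs(tval[j]), df=n - 2)

    table = pd.DataFrame(
        {
            "variant": gsub.variants["id"],
            "chrom": gsub.variants["chrom"],
            "pos": gsub.variants["pos"],
            "maf": gsub.compute_maf(),
            "beta": beta,
            "se": se,
            "t": tval,
            "p": pval,
        }
    )
    finite = table["p"].notna()
    lam = genomic_control(table.loc[finite, "p"].to_numpy()) if finite.sum() >= 100 else np.nan
    return ScanResult(table=table, trait=trait, lambda_gc=lam, n_used=n)


def genomic_control(p_values: np.ndarray) -> float:
    """Median-based inflation factor of 1-df chi-square statistics."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        warnings.warn("genomic control on fewer than 100 p-values", stacklevel=2)
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# Multi-trait association
# ---------------------------------------------------------------------------

def trait_correlation(t_matrix, stride: int = 1) -> pd.DataFrame:
    """Trait-by-trait Pearson correlation of signed t-values.

    ``t_matrix`` is (variants x traits), a DataFrame or array; ``stride``
    subsamples every stride-th variant (10/100 reproduce the robustness
    check against using all variants).
    """
    if isinstance(t_matrix, pd.DataFrame):
        names = list(t_matrix.columns)
        arr = t_matrix.to_numpy(float)
    else:
        arr = np.asarray(t_matrix, dtype=float)
        names = [f"trait{i + 1}" for i in range(arr.shape[1])]
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    arr = arr[::stride]
    if arr.shape[0] < 100:
        warnings.warn("fewer than 100 variants after striding", stacklevel=2)
    if np.any(arr.std(axis=0) == 0):
        raise ValueError("constant t-value column: correlation undefined")
    V = np.corrcoef(arr, rowvar=False)
    return pd.DataFrame(V, index=names, columns=names)


def multi_trait_chisq(t_vector, V) -> tuple[float, float]:
    """Multi-trait chi-square t' V^{-1} t with df = number of traits."""
    t = np.asarray(t_vector, dtype=float).reshape(-1)
    Vm = V.to_numpy() if isinstance(V, pd.DataFrame) else np.asarray(V, dtype=float)
    if np.array_equal(Vm, np.eye(len(t))):
        stat = float(np.sum(t**2))
        return stat, float(stats.chi2.sf(stat, df=len(t)))
    try:
        cho = linalg.cho_factor(Vm)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "trait correlation matrix is singular; prune collinear traits"
        ) from err
    stat = float(t @ linalg.cho_solve(cho, t))
    p = float(stats.chi2.sf(stat, df=len(t)))
    return stat, p


def multi_trait_scan(scans: list[ScanResult], V: pd.DataFrame | None = None) -> ScanResult:
    """Chi-square multi-trait test per variant from aligned single-trait scans."""
    base = scans[0].table
    t_mat = pd.DataFrame(
        {s.trait: s.table.set_index("variant")["t"] for s in scans}
    ).dropna()
    if V is None:
        V = trait_correlation(t_mat)
    Vm = V.loc[[s.trait for s in scans], [s.trait for s in scans]].to_numpy()
    cho = linalg.cho_factor(Vm)
    T = t_mat.to_numpy()
    stat = np.einsum("ij,ij->i", T, linalg.cho_solve(cho, T.T).T)
    p = stats.chi2.sf(stat, df=T.shape[1])
    meta = base.set_index("variant").loc[t_mat.index, ["chrom", "pos", "maf"]]
    table = pd.DataFrame(
        {
            "variant": t_mat.index,
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "maf": meta["maf"].to_numpy(),
            "beta": np.nan,
            "se": np.nan,
            "t": np.sqrt(np.maximum(stat, 0.0)),
            "p": p,
        }
    ).reset_index(drop=True)
    lam = genomic_control(p) if len(p) >= 100 else np.nan
    return ScanResult(
        table=table, trait="+".join(s.trait for s in scans), lambda_gc=lam
    )


def cluster_traits(V: pd.DataFrame, n_groups: int | None = None) -> dict:
    """Average-linkage hierarchical clustering on distance 1 - |correlation|."""
    Vm = V.to_numpy() if isinstance(V, pd.DataFrame) else np.asarray(V, float)
    names = list(V.columns) if isinstance(V, pd.DataFrame) else [
        f"trait{i + 1}" for i in range(Vm.shape[0])
    ]
    dist = 1.0 - np.abs(Vm)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    condensed = np.clip(condensed, 0.0, None)
    Z = hierarchy.linkage(condensed, method="average")
    out = {"linkage": Z, "traits": names, "linkage_method": "average"}
    if n_groups is not None:
        labels = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
        out["groups"] = dict(zip(names, (int(g) for g in labels)))
    return out


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def detect_peaks(
    scan: ScanResult,
    alpha: float = 5e-8,
    merge_window: int = 1_000_000,
    min_cluster: int = 3,
) -> list[QtlRegion]:
    """QTL regions from clusters of genome-wide-significant variants.

    Significant variants within ``merge_window`` of each other are grouped;
    groups with fewer than ``min_cluster`` members (sporadic significant
    variants) are discarded.  The lead is the smallest-p variant.
    """
    tab = scan.table
    sig = tab[tab["p"] < alpha]
    regions: list[QtlRegion] = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_window)
        for chunk in np.split(np.arange(len(pos)), breaks + 1):
            if len(chunk) < min_cluster:
                continue
            block = sub.iloc[chunk]
            lead = block.loc[block["p"].idxmin()]
            regions.append(
                QtlRegion(
                    chrom=str(chrom),
                    start=int(block["pos"].min()),
                    end=int(block["pos"].max()),
                    lead_variant=str(lead["variant"]),
                    lead_pos=int(lead["pos"]),
                    lead_p=float(lead["p"]),
                    traits=[scan.trait],
                    source="single-trait",
                    n_significant=len(block),
                )
            )
    return regions
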