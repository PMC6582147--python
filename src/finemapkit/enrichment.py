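"""Enrichment of causal effects in functional-annotation categories.

For an annotation scheme partitioning variants into categories, p_C is the
probability that a causal variant falls in category C and q_C the same for
a non-causal variant; the enrichment is E_C = p_C / q_C.  q_C is estimated
by genome-wide category frequencies.  p_C is the maximum-likelihood
estimate under a mixture over which variant in each independent signal is
causal; because each signal's equal-prior PPCs are proportional to the
per-variant marginal likelihoods, the likelihood only needs those PPCs, and
EM (responsibilities = annotation-updated PPCs; M-step = mean per-signal
PPC mass per category) maximises it exactly.  The same update produces the
annotation-aware prior for PPC refinement, so estimation and prior
construction share one code path.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "EnrichmentModel",
    "estimate_qc",
    "estimate_pc",
    "enrichment_ratio",
    "bootstrap_ci",
    "make_priors",
    "ratio_permutation_test",
    "gene_location_classes",
]

_IMPACT_ORDER = ["HIGH", "MODERATE", "LOW", "MODIFIER"]


@dataclasses.dataclass
class AnnotationMap:
    """One category per variant for one annotation scheme."""

    scheme: str
    categories: pd.Series  # index: variant id, values: category label

    def __post_init__(self):
        self.categories = self.categories.astype(str)
        if self.categories.index.duplicated().any():
            raise ValueError("variant annotated more than once in one scheme")

    @property
    def category_names(self) -> list[str]:
        return sorted(self.categories.unique())

    def of(self, variant_ids) -> np.ndarray:
        return self.categories.reindex(variant_ids).to_numpy()

    @classmethod
    def from_tsv(cls, path, scheme: str | None = None) -> "AnnotationMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"variant_id", "scheme", "category"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation TSV needs columns {sorted(required)}")
        if scheme is None:
            schemes = df["scheme"].unique()
            if len(schemes) != 1:
                raise ValueError(f"multiple schemes present: {list(schemes)}")
            scheme = schemes[0]
        sub = df[df["scheme"] == scheme]
        return cls(scheme=scheme, categories=sub.set_index("variant_id")["category"])

    def cross(self, other: "AnnotationMap") -> "AnnotationMap":
        """Cross-product scheme by label concatenation (e.g. impact x constraint)."""
        joined = self.categories.str.cat(
            other.categories.reindex(self.categories.index), sep="&"
        ).dropna()
        return AnnotationMap(scheme=f"{self.scheme}x{other.scheme}", categories=joined)


@dataclasses.dataclass
class EnrichmentModel:
    """Category probabilities for causal (p) and non-causal (q) variants."""

    p_c: pd.Series
    q_c: pd.Series
    e_c: pd.Series
    ci: pd.DataFrame | None = None  # columns: low, high (on the E_C scale)
    n_signals: int = 0
    scheme: str = ""

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"p_c": self.p_c, "q_c": self.q_c, "e_c": self.e_c})
        if self.ci is not None:
            out = out.join(self.ci)
        out.index.name = "category"
        return out


def estimate_qc(annotation: AnnotationMap, variant_ids=None) -> pd.Series:
    """Genome-wide category frequencies (empty categories kept at 0)."""
    cats = (
        annotation.categories
        if variant_ids is None
        else annotation.categories.reindex(variant_ids)
    )
    if cats.isna().any():
        missing = cats.index[cats.isna()][:5]
        raise ValueError(f"uncategorised variants, e.g. {list(missing)}")
    counts = cats.value_counts()
    q = counts / counts.sum()
    if (q == 0).any():
        logger.warning("empty annotation categories: %s", list(q.index[q == 0]))
    return q.sort_index()


def _pad_signals(signal_ppcs, signal_cats, cat_index):
    """Stack per-signal PPC vectors into (S, Jmax) arrays with -1 category pads."""
    S = len(signal_ppcs)
    jmax = max(len(p) for p in signal_ppcs)
    P = np.zeros((S, jmax))
    C = np.full((S, jmax), -1, dtype=int)
    code = {c: k for k, c in enumerate(cat_index)}
    for i, (ppc, cats) in enumerate(zip(signal_ppcs, signal_cats)):
        ppc = np.asarray(ppc, dtype=float)
        P[i, : len(ppc)] = ppc / ppc.sum()
        C[i, : len(ppc)] = [code[c] for c in cats]
    return P, C


def _em_pc(P, C, q_vec, weights=None, tol=1e-8, max_iter=10_000):
    """Vectorised EM for the causal-category probabilities.

    P: (S, J) equal-prior PPCs (padded with zeros); C: (S, J) category codes
    (-1 pads); q_vec: (K,) background frequencies; weights: (B, S) signal
    weights (bootstrap multiplicities), default all-ones single batch.
    Returns p of shape (B, K) and the final log-likelihoods (B,).
    """
    S, J = P.shape
    K = len(q_vec)
    if weights is None:
        weights = np.ones((1, S))
    B = weights.shape[0]
    Csafe = np.where(C >= 0, C, 0)
    valid = C >= 0
    q_at = np.where(valid, q_vec[Csafe], 1.0)
    q_at = np.where(q_at > 0, q_at, np.inf)  # q=0 category cannot host mass
    onehot = np.zeros((K, S, J))
    for k in range(K):
        onehot[k] = valid & (Csafe == k)

    p = np.tile(q_vec / q_vec.sum(), (B, 1))  # start at the background
    w_tot = weights.sum(axis=1)
    ll_prev = None
    for it in range(max_iter):
        lift = p[:, Csafe] / q_at[None, :, :]  # (B, S, J) gather of p_{c_sj}/q_{c_sj}
        w = P[None, :, :] * np.where(valid[None, :, :], lift, 0.0)
        norm = w.sum(axis=2, keepdims=True)
        norm = np.where(norm > 0, norm, 1.0)
        r = w / norm  # responsibilities (B, S, J)
        new_p = np.einsum("ksj,bsj,bs->bk", onehot, r, weights) / w_tot[:, None]
        ll = (weights * np.log(np.maximum(norm[..., 0], 1e-300))).sum(axis=1)
        delta = np.abs(new_p - p).max()
        p = new_p
        if ll_prev is not None and delta < tol:
            return p, ll
        ll_prev = ll
    raise RuntimeError(
        f"EM did not converge in {max_iter} iterations (last max |dp| = {delta:.3g})"
    )


def estimate_pc(
    signal_ppcs: list,
    signal_categories: list,
    q_c: pd.Series,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> pd.Series:
    """MLE of the causal-category probabilities {p_C} from equal-prior PPCs.

    ``signal_ppcs[i]`` and ``signal_categories[i]`` give the equal-prior PPC
    vector and per-variant categories of independent signal i.  The
    estimate lies on the probability simplex.
    """
    if not len(signal_ppcs):
        raise ValueError("need at least one signal")
    cat_index = list(q_c.sort_index().index)
    q_vec = q_c.sort_index().to_numpy(float)
    P, C = _pad_signals(signal_ppcs, signal_categories, cat_index)
    p, _ = _em_pc(P, C, q_vec, tol=tol, max_iter=max_iter)
    return pd.Series(p[0], index=cat_index, name="p_c")


def enrichment_ratio(p_c: pd.Series, q_c: pd.Series) -> pd.Series:
    """E_C = p_C / q_C; categories with q_C = 0 are reported as NaN."""
    q = q_c.reindex(p_c.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = p_c / q
    return e.where(q > 0, np.nan).rename("e_c")


def bootstrap_ci(
    signal_ppcs: list,
    signal_categories: list,
    q_c: pd.Series,
    n_boot: int = 1000,
    level: float = 0.95,
    min_category_freq: float = 0.01,
    rng=None,
    chunk: int = 200,
) -> EnrichmentModel:
    """Percentile-bootstrap confidence intervals for the enrichment ratios.

    Signals are resampled with replacement ``n_boot`` times and the MLE
    rerun on each resample (resampling is implemented as multinomial signal
    weights, so all resamples share one vectorised EM).  Very small
    categories — genome-wide frequency below ``min_category_freq`` with no
    summed PPC mass — are removed before resampling and reported in the
    model's q with a flag, mirroring their exclusion from the MLE to avoid
    non-convergence.
    """
    if len(signal_ppcs) < 10:
        warnings.warn("bootstrap on fewer than 10 signals", stacklevel=2)
    q_c = q_c.sort_index()
    mass = {c: 0.0 for c in q_c.index}
    for ppc, cats in zip(signal_ppcs, signal_categories):
        for v, c in zip(np.asarray(ppc, float), cats):
            mass[c] += v
    small = [
        c for c in q_c.index if q_c[c] < min_category_freq and mass[c] <= 1e-12
    ]
    use_cats = [c for c in q_c.index if c not in small]
    if small:
        logger.info("bootstrap_ci: dropping small categories %s", small)

    def restrict(ppc, cats):
        keep = [i for i, c in enumerate(cats) if c in use_cats]
        return np.asarray(ppc, float)[keep], [cats[i] for i in keep]

    restricted = [restrict(p, c) for p, c in zip(signal_ppcs, signal_categories)]
    restricted = [(p, c) for p, c in restricted if len(p) and p.sum() > 0]
    q_use = q_c[use_cats] / q_c[use_cats].sum()
    P, C = _pad_signals(
        [p for p, _ in restricted], [c for _, c in restricted], use_cats
    )
    q_vec = q_use.to_numpy()
    p_hat, _ = _em_pc(P, C, q_vec)
    p_hat = pd.Series(p_hat[0], index=use_cats)

    rng = np.random.default_rng(rng)
    S = P.shape[0]
    boots = []
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        weights = rng.multinomial(S, np.full(S, 1.0 / S), size=b).astype(float)
        p_b, _ = _em_pc(P, C, q_vec, weights=weights)
        boots.append(p_b)
        done += b
    boot_p = np.vstack(boots)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_e = boot_p / q_vec[None, :]
    alpha = (1.0 - level) / 2.0
    low = np.quantile(boot_e, alpha, axis=0)
    high = np.quantile(boot_e, 1.0 - alpha, axis=0)
    ci = pd.DataFrame({"low": low, "high": high}, index=use_cats)

    e_hat = enrichment_ratio(p_hat, q_use)
    return EnrichmentModel(
        p_c=p_hat,
        q_c=q_use,
        e_c=e_hat,
        ci=ci,
        n_signals=S,
    )


def make_priors(p_c: pd.Series, q_c: pd.Series, categories) -> np.ndarray:
    """Annotation prior over one signal's candidate set.

    The joint prior for 'variant j is the causal one' is
    p_{c_j} * prod_{j' != j} q_{c_j'}; dividing by the shared product
    prod_j q_{c_j} leaves the per-variant weight p_{c_j}/q_{c_j}, which is
    returned normalised over the set.
    """
    cats = list(categories)
    q = q_c.reindex(cats)
    if q.isna().any() or (q <= 0).any():
        bad = [c for c, v in zip(cats, q) if not v > 0]
        raise ValueError(f"prior undefined for categories with q_c = 0: {bad}")
    w = (p_c.reindex(cats) / q).to_numpy(float)
    return w / w.sum()


def update_ppc(ppc: pd.Series, priors: np.ndarray) -> pd.Series:
    """Annotation-updated PPC: equal-prior PPC times prior, renormalised.

    This is exactly one EM responsibility step, so prior construction and
    estimation agree by construction.  A constant prior (the one-category
    reduction) leaves the PPC untouched, bit for bit.
    """
    priors = np.asarray(priors, float)
    if np.ptp(priors) == 0.0:
        return ppc.copy()
    w = ppc.to_numpy(float) * priors
    return pd.Series(w / w.sum(), index=ppc.index, name="ppc")


def ratio_permutation_test(
    group_a: tuple[list, list],
    group_b: tuple[list, list],
    q_c: pd.Series,
    category: str,
    n_perm: int = 1000,
    rng=None,
) -> dict:
    """Permutation test of E_C(A) / E_C(B) between two signal groups.

    ``group_a``/``group_b`` are (signal_ppcs, signal_categories) pairs.  The
    null distribution permutes group labels across signals; the two-sided
    p-value uses the add-one correction on |log ratio|.  Permutations with
    an undefined ratio are dropped (with a warning above 10%).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    ppcs_a, cats_a = group_a
    ppcs_b, cats_b = group_b
    if not len(ppcs_a) or not len(ppcs_b):
        raise ValueError("both groups must be nonempty")

    def group_ec(ppcs, cats):
        p = estimate_pc(ppcs, cats, q_c)
        e = enrichment_ratio(p, q_c)
        val = float(e.get(category, np.nan))
        return val

    obs_a = group_ec(ppcs_a, cats_a)
    obs_b = group_ec(ppcs_b, cats_b)
    if not np.isfinite(obs_a) or not np.isfinite(obs_b) or obs_b == 0 or obs_a == 0:
        raise ValueError("observed enrichment ratio undefined")
    obs = obs_a / obs_b

    all_ppcs = list(ppcs_a) + list(ppcs_b)
    all_cats = list(cats_a) + list(cats_b)
    n_a = len(ppcs_a)
    n_tot = len(all_ppcs)
    rng = np.random.default_rng(rng)
    null = []
    dropped = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        ia, ib = perm[:n_a], perm[n_a:]
        try:
            ea = group_ec([all_ppcs[i] for i in ia], [all_cats[i] for i in ia])
            eb = group_ec([all_ppcs[i] for i in ib], [all_cats[i] for i in ib])
        except (ValueError, RuntimeError):
            dropped += 1
            continue
        if not np.isfinite(ea) or not np.isfinite(eb) or eb == 0 or ea == 0:
            dropped += 1
            continue
        null.append(ea / eb)
    if dropped > 0.1 * n_perm:
        warnings.warn(
            f"{dropped}/{n_perm} permutations had undefined ratios", stacklevel=2
        )
    null = np.array(null)
    exceed = np.sum(np.abs(np.log(null)) >= abs(np.log(obs)))
    p = float((exceed + 1) / (len(null) + 1))
    return {
        "observed_ratio": obs,
        "e_a": obs_a,
        "e_b": obs_b,
        "p_value": p,
        "n_perm_used": int(len(null)),
    }


# ---------------------------------------------------------------------------
# Gene-location annotation classes
# ---------------------------------------------------------------------------

def gene_location_classes(
    variants: pd.DataFrame,
    gff3_features: pd.DataFrame,
    flank: int = 2000,
    scheme: str = "gene_location",
) -> AnnotationMap:
    """Classify variants as CDS / 5'UTR+upstream / intron / 3'UTR+downstream / other.

    Built from GFF3 gene, CDS, exon and UTR features; the 5' class includes
    ``flank`` bp upstream of the gene and the 3' class ``flank`` bp
    downstream (strand-aware).  Precedence: CDS, then the UTR classes, then
    intron, else other.
    """
    from .io import derive_introns

    def collect(ftype):
        sub = gff3_features[gff3_features["type"] == ftype]
        return sub[["chrom", "start", "end"]]

    cds = collect("CDS")
    utr5 = collect("five_prime_UTR")
    utr3 = collect("three_prime_UTR")
    genes = gff3_features[gff3_features["type"] == "gene"]
    introns = derive_introns(gff3_features)

    up5 = []
    down3 = []
    for _, g in genes.iterrows():
        if g["strand"] == "-":
            up5.append({"chrom": g["chrom"], "start": g["end"] + 1, "end": g["end"] + flank})
            down3.append({"chrom": g["chrom"], "start": max(g["start"] - flank, 1), "end": g["start"] - 1})
        else:
            up5.append({"chrom": g["chrom"], "start": max(g["start"] - flank, 1), "end": g["start"] - 1})
            down3.append({"chrom": g["chrom"], "start": g["end"] + 1, "end": g["end"] + flank})
    utr5 = pd.concat([utr5, pd.DataFrame(up5)], ignore_index=True) if len(up5) else utr5
    utr3 = pd.concat([utr3, pd.DataFrame(down3)], ignore_index=True) if len(down3) else utr3

    def in_any(chrom, pos, table):
        if not len(table):
            return False
        sub = table[table["chrom"].astype(str) == chrom]
        return bool(((sub["start"] <= pos) & (pos <= sub["end"])).any())

    labels = {}
    for _, v in variants.iterrows():
        chrom, pos = str(v["chrom"]), int(v["pos"])
        if in_any(chrom, pos, cds):
            lab = "CDS"
        elif in_any(chrom, pos, utr5):
            lab = "UTR5_upstream"
        elif in_any(chrom, pos, utr3):
            lab = "UTR3_downstream"
        elif in_any(chrom, pos, introns):
            lab = "intron"
        else:
            lab = "other"
        labels[v["id"]] = lab
    return AnnotationMap(scheme=scheme, categories=pd.Series(labels))
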