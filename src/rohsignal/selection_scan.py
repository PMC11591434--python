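"""Selection-signature scan: Fst outliers intersected with ROH islands.

Per-locus Weir-Cockerham Fst values are compared against a fitted neutral
distribution: the uncorrected estimator (scaled by its degrees of freedom)
is modelled as a scaled chi-square, ``fst * df / fst_bar ~ chi2(df)``, with
``df`` and ``fst_bar`` fit by trimmed maximum likelihood on the central
part of the empirical distribution (low-heterozygosity loci excluded).
Right-tail p-values flag unusually differentiated loci.  Selection
signatures are the loci simultaneously in the top fraction of ROH
incidence (default 5%) and the top fraction of smallest Fst p-values
(default 1%), optionally annotated against local BED/GFF feature files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix, PopulationMap, logger
from .population_structure import weir_cockerham_components, wc_fst_nocorr
from .roh_analysis import ROHIncidence


@dataclass
class FstOutlierResult:
    """Per-locus Fst table plus the fitted neutral parameters."""

    table: pd.DataFrame = field(repr=False)  # id, chrom, pos, fst, fst_nocorr, het, p_value
    df_hat: float = float("nan")
    fst_bar: float = float("nan")


@dataclass
class SelectionSignature:
    marker_id: str
    chrom: str
    pos: int
    roh_incidence_pct: float
    fst: float
    p_value: float
    features: list[str] = field(default_factory=list)
    nearest_feature: str | None = None
    nearest_distance_bp: int | None = None


class NeutralFitError(RuntimeError):
    """Raised when the neutral-Fst fit cannot converge or is degenerate."""


# ---------------------------------------------------------------------------
# Per-locus Fst
# ---------------------------------------------------------------------------


def per_locus_fst(
    gm: GenotypeMatrix, popmap: PopulationMap | None = None
) -> pd.DataFrame:
    """Per-locus multi-population WC84 Fst, its uncorrected variant and He.

    Loci informative in fewer than two populations are excluded (logged).
    """
    if popmap is not None:
        gm = gm.attach_popmap(popmap)
    a, b, c = weir_cockerham_components(gm)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / (a + b + c)
    fst_nocorr, het = wc_fst_nocorr(gm)
    out = gm.loci[["id", "chrom", "pos"]].copy()
    out["fst"] = fst
    out["fst_nocorr"] = fst_nocorr
    out["het"] = het
    usable = np.isfinite(fst_nocorr)
    n_drop = int((~usable).sum())
    if n_drop:
        logger.info("per_locus_fst: excluding %d uninformative loci", n_drop)
    return out[usable].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Neutral-distribution fit
# ---------------------------------------------------------------------------


def _trimmed_nll(theta, x, lo, hi):
    """Negative log-likelihood of a doubly-truncated scaled chi-square."""
    log_df, log_fb = theta
    df, fb = np.exp(log_df), np.exp(log_fb)
    scale = fb / df
    ll = stats.chi2.logpdf(x / scale, df) - np.log(scale)
    norm = stats.chi2.cdf(hi / scale, df) - stats.chi2.cdf(lo / scale, df)
    if norm <= 0 or not np.isfinite(norm):
        return 1e12
    return float(-(ll.sum() - x.size * np.log(norm)))


def fit_neutral_fst(
    fst_nocorr: np.ndarray,
    het: np.ndarray,
    trim_fraction: float = 0.05,
    het_min: float = 0.1,
) -> tuple[float, float]:
    """Fit the neutral scaled chi-square model to uncorrected Fst values.

    Loci with pooled expected heterozygosity below *het_min* are dropped
    (low-He loci have noisy, biased Fst).  The upper and lower
    *trim_fraction* tails of the remaining Fst distribution are removed and
    ``df, fst_bar`` estimated by maximum likelihood on the doubly-truncated
    density, so outliers in either tail do not drag the neutral fit.

    Returns ``(df_hat, fst_bar)``.
    """
    x = np.asarray(fst_nocorr, dtype=float)
    h = np.asarray(het, dtype=float)
    keep = np.isfinite(x) & np.isfinite(h) & (h >= het_min) & (x > 0)
    x = x[keep]
    if x.size < 100:
        raise NeutralFitError(
            f"only {x.size} usable loci after the heterozygosity filter; need >= 100"
        )
    xs = np.sort(x)
    n_trim = int(np.floor(trim_fraction * xs.size))
    core = xs[n_trim : xs.size - n_trim] if n_trim else xs
    lo, hi = float(core[0]), float(core[-1])
    if np.var(core) == 0:
        raise NeutralFitError("degenerate input: trimmed Fst values are constant")
    mean, var = float(core.mean()), float(core.var())
    df0 = max(2 * mean * mean / var, 0.2)
    theta0 = np.array([np.log(df0), np.log(mean)])
    res = optimize.minimize(
        _trimmed_nll, theta0, args=(core, lo, hi), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    if not res.success:
        raise NeutralFitError(f"neutral fit did not converge: {res.message}")
    df_hat, fst_bar = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    if not (df_hat > 0 and fst_bar > 0):
        raise NeutralFitError("neutral fit produced non-positive parameters")
    return df_hat, fst_bar


def fst_pvalues(fst_nocorr: np.ndarray, df_hat: float, fst_bar: float) -> np.ndarray:
    """Right-tail p-values under the fitted neutral distribution.

    ``p = P(chi2_df >= fst * df / fst_bar)``; non-positive Fst maps to 1.
    """
    if not (df_hat > 0 and fst_bar > 0):
        raise ValueError("fitted parameters must be positive")
    x = np.asarray(fst_nocorr, dtype=float)
    p = np.ones_like(x)
    pos = np.isfinite(x) & (x > 0)
    p[pos] = stats.chi2.sf(x[pos] * df_hat / fst_bar, df_hat)
    return p


def fst_outlier_scan(
    gm: GenotypeMatrix,
    popmap: PopulationMap | None = None,
    trim_fraction: float = 0.05,
    het_min: float = 0.1,
) -> FstOutlierResult:
    """Full outlier scan: per-locus Fst, neutral fit, p-values."""
    table = per_locus_fst(gm, popmap)
    df_hat, fst_bar = fit_neutral_fst(
        table["fst_nocorr"].to_numpy(), table["het"].to_numpy(),
        trim_fraction=trim_fraction, het_min=het_min,
    )
    table = table.copy()
    table["p_value"] = fst_pvalues(table["fst_nocorr"].to_numpy(), df_hat, fst_bar)
    return FstOutlierResult(table, df_hat, fst_bar)


# ---------------------------------------------------------------------------
# Percentile selection and intersection
# ---------------------------------------------------------------------------


def select_top_fraction(
    values: np.ndarray, fraction: float, direction: str = "highest"
) -> np.ndarray:
    """Indices of the top *fraction* of values, ties at the cut included.

    ``direction='lowest'`` selects the smallest values (p-values),
    ``'highest'`` the largest (incidence).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0,1)")
    v = np.asarray(values, dtype=float)
    if direction == "lowest":
        thr = np.quantile(v, fraction)
        return np.flatnonzero(v <= thr)
    if direction == "highest":
        thr = np.quantile(v, 1 - fraction)
        return np.flatnonzero(v >= thr)
    raise ValueError("direction must be 'lowest' or 'highest'")


def intersect_signatures(
    roh_top: np.ndarray,
    fst_top: np.ndarray,
    incidence: ROHIncidence,
    fst_table: pd.DataFrame,
) -> list[SelectionSignature]:
    """Loci present in both percentile sets, as annotated-ready records.

    *roh_top* holds locus indices into the incidence table; *fst_top* holds
    row indices into *fst_table*.  The intersection is taken on marker ids,
    so the two inputs may cover different locus subsets of one universe.
    Output is sorted by (chrom, pos); the operation is order-independent
    and idempotent.
    """
    inc_frame = incidence.to_frame()
    roh_ids = set(inc_frame["id"].iloc[np.asarray(roh_top, dtype=int)])
    fst_rows = fst_table.iloc[np.asarray(fst_top, dtype=int)]
    hits = fst_rows[fst_rows["id"].isin(roh_ids)]
    inc_by_id = inc_frame.set_index("id")["incidence_pct"]
    sigs = [
        SelectionSignature(
            marker_id=row["id"],
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            roh_incidence_pct=float(inc_by_id[row["id"]]),
            fst=float(row["fst"]),
            p_value=float(row["p_value"]),
        )
        for _, row in hits.iterrows()
    ]
    sigs.sort(key=lambda s: (s.chrom, s.pos))
    return sigs


def signatures_to_frame(signatures: list[SelectionSignature]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker_id": s.marker_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "roh_incidence_pct": s.roh_incidence_pct,
                "fst": s.fst,
                "p_value": s.p_value,
                "features": ";".join(s.features),
                "nearest_feature": s.nearest_feature or "",
                "nearest_distance_bp": (
                    s.nearest_distance_bp if s.nearest_distance_bp is not None else ""
                ),
            }
            for s in signatures
        ],
        columns=[
            "marker_id", "chrom", "pos", "roh_incidence_pct", "fst", "p_value",
            "features", "nearest_feature", "nearest_distance_bp",
        ],
    )


# ---------------------------------------------------------------------------
# Local annotation
# ---------------------------------------------------------------------------


def read_features(path) -> pd.DataFrame:
    """Read genomic intervals from a local BED or GFF/GTF file.

    Returns columns ``chrom, start, end, name`` with 1-based inclusive
    coordinates (BED's half-open 0-based records are converted on read).
    """
    path = str(path)
    rows = []
    is_gff = path.endswith((".gff", ".gff3", ".gtf"))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if is_gff:
                    if len(parts) < 9:
                        raise ValueError("GFF needs 9 columns")
                    chrom, start, end = parts[0], int(parts[3]), int(parts[4])
                    attrs = parts[8]
                    name = _gff_name(attrs) or f"{chrom}:{start}-{end}"
                else:
                    if len(parts) < 3:
                        raise ValueError("BED needs >= 3 columns")
                    chrom = parts[0]
                    start, end = int(parts[1]) + 1, int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
                if end < start:
                    raise ValueError("interval end before start")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed interval ({exc})") from exc
            rows.append({"chrom": str(chrom), "start": start, "end": end, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _gff_name(attrs: str) -> str | None:
    for key in ("Name=", "gene_name=", "ID=", "gene_id "):
        for fieldv in attrs.replace("; ", ";").split(";"):
            fieldv = fieldv.strip()
            if fieldv.startswith(key):
                return fieldv[len(key):].strip('"')
    return None


def annotate_signatures(
    signatures: list[SelectionSignature],
    features: pd.DataFrame,
    window_kb: float = 0.0,
) -> list[SelectionSignature]:
    """Attach overlapping and nearest features to each signature.

    A feature "overlaps" when its interval intersects ``pos +/- window_kb``.
    The nearest feature on the same chromosome is reported with its distance
    (0 when overlapping); signatures on feature-less chromosomes keep an
    empty annotation.
    """
    from intervaltree import IntervalTree

    win_bp = window_kb * 1000.0
    trees: dict[str, IntervalTree] = {}
    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, grp in features.groupby("chrom", sort=False):
        tree = IntervalTree()
        for _, f in grp.iterrows():
            tree.addi(f["start"], f["end"] + 1, f["name"])  # half-open
        trees[str(chrom)] = tree
        by_chrom[str(chrom)] = grp
    for sig in signatures:
        sig.features = []
        sig.nearest_feature = None
        sig.nearest_distance_bp = None
        tree = trees.get(sig.chrom)
        if tree is None:
            continue
        lo, hi = sig.pos - win_bp, sig.pos + win_bp
        hits = sorted(tree.overlap(lo, hi + 1), key=lambda iv: (iv.begin, iv.data))
        sig.features = [iv.data for iv in hits]
        grp = by_chrom[sig.chrom]
        dist = np.maximum(
            grp["start"].to_numpy() - sig.pos, sig.pos - grp["end"].to_numpy()
        )
        dist = np.maximum(dist, 0)
        k = int(np.argmin(dist))
        sig.nearest_feature = str(grp["name"].iloc[k])
        sig.nearest_distance_bp = int(dist[k])
    return signatures
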