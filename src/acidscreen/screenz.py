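"""Differential gene-essentiality scoring for pooled CRISPR screens.

Scores how each gene knockout changes fitness between two extracellular-pH
conditions from sgRNA count matrices, following the normZ scheme used for
chemogenetic-interaction screens:

1. per-sample normalization to a fixed read scale with a pseudocount,
2. per-guide log2 fold change (treated vs control) within each replicate,
3. an empirical-Bayes standard deviation of the fold change, estimated in a
   sliding window over guides ranked by control abundance and forced to be
   non-decreasing toward low abundance (low-count guides are noisier),
4. guide Z = fc / eb_sd, pooled over guide x replicate observations,
5. gene normZ = sum(Z)/sqrt(n_obs), robustly standardized across genes,
6. directional normal-tail p-values with Benjamini-Hochberg FDR per
   direction; hits called at FDR < 0.1 by default.

Depleted genes (negative normZ) are selectively essential in the treated
condition; enriched genes (positive normZ) are selectively dispensable.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PSEUDOCOUNT = 5
DEFAULT_SCALE = 1e7
DEFAULT_HALF_WINDOW = 500
DEFAULT_FDR = 0.1
_SD_FLOOR = 1e-6
_MAD_TO_SD = 1.4826022185056018  # 1/Phi^-1(3/4)

_SAMPLE_RE = re.compile(
    r"^T(?P<tp>\d+)(?:_ph(?P<ph>\d+(?:\.\d+)?))?_r(?P<rep>\d+)$")


@dataclass
class CountMatrix:
    """sgRNA counts with per-sample metadata.

    ``counts``: DataFrame indexed by guide id, first column ``gene`` then one
    integer column per sample. ``meta``: DataFrame indexed by sample name
    with columns timepoint (e.g. "T0", "T11"), ph (float or NaN for the
    pre-treatment pool), replicate (int).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if "gene" not in self.counts.columns:
            raise ValueError("counts must carry a 'gene' column")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate guide id: {dup!r}")
        vals = self.counts[self.samples]
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts[self.samples] = arr.astype(np.int64)
        if (self.counts[self.samples].to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.samples if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    @property
    def samples(self) -> list[str]:
        return [c for c in self.counts.columns if c != "gene"]

    @property
    def guides(self) -> pd.Index:
        return self.counts.index

    def samples_for(self, *, timepoint: str | None = None,
                    ph: float | None = None,
                    replicate: int | None = None) -> list[str]:
        sel = pd.Series(True, index=self.meta.index)
        if timepoint is not None:
            sel &= self.meta["timepoint"] == timepoint
        if ph is not None:
            sel &= np.isclose(self.meta["ph"].astype(float), ph)
        if replicate is not None:
            sel &= self.meta["replicate"] == replicate
        return list(self.meta.index[sel])


def parse_sample_name(name: str) -> dict:
    """Parse names like ``T0_r1`` or ``T11_ph6.63_r2`` into metadata."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse sample name {name!r}; expected "
                         "T<day>[_ph<pHe>]_r<replicate>")
    return {"timepoint": f"T{m.group('tp')}",
            "ph": float(m.group("ph")) if m.group("ph") else np.nan,
            "replicate": int(m.group("rep"))}


def read_counts(path, meta: pd.DataFrame | None = None) -> CountMatrix:
    """Read a GUIDE/GENE/sample TSV into a validated CountMatrix.

    If no metadata table is supplied, sample names are parsed with
    :func:`parse_sample_name`.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0].upper() != "GUIDE" or df.columns[1].upper() != "GENE":
        raise ValueError("expected a TSV starting with GUIDE and GENE columns")
    df = df.rename(columns={df.columns[0]: "guide", df.columns[1]: "gene"})
    bad = df["guide"].isna() | df["gene"].isna()
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} malformed rows")
        df = df[~bad]
    dup = df["guide"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate guide id: {df['guide'][dup].iloc[0]!r}")
    df = df.set_index("guide")
    sample_cols = [c for c in df.columns if c != "gene"]
    for c in sample_cols:
        col = pd.to_numeric(df[c], errors="raise")
        if not np.allclose(col, np.round(col)):
            raise ValueError(f"non-integer counts in sample {c!r}")
        df[c] = col.astype(np.int64)
    if meta is None:
        meta = pd.DataFrame([parse_sample_name(s) for s in sample_cols],
                            index=pd.Index(sample_cols, name="sample"))
    return CountMatrix(counts=df, meta=meta)


def write_counts(m: CountMatrix, path) -> None:
    out = m.counts.reset_index()
    out = out.rename(columns={"guide": "GUIDE", "gene": "GENE"})
    out.to_csv(path, sep="\t", index=False)


def normalize_counts(m: CountMatrix, *, pseudocount: int = DEFAULT_PSEUDOCOUNT,
                     scale: float = DEFAULT_SCALE) -> pd.DataFrame:
    """Pseudocounted per-sample normalization to a fixed read scale.

    value = (count + pseudocount) * scale / (sample_total + pseudocount * n_guides),
    so every sample's normalized total is exactly ``scale``.
    """
    counts = m.counts[m.samples].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = [s for s, t in zip(m.samples, totals) if t <= 0]
        raise ValueError(f"samples with zero total reads: {bad}")
    n_guides = counts.shape[0]
    norm = (counts + pseudocount) * scale / (totals + pseudocount * n_guides)
    return pd.DataFrame(norm, index=m.guides, columns=m.samples)


def guide_fold_changes(norm: pd.DataFrame, treated_sample: str,
                       control_sample: str) -> pd.Series:
    """Per-guide log2 fold change of treated vs control normalized reads."""
    for s in (treated_sample, control_sample):
        if s not in norm.columns:
            raise KeyError(f"sample {s!r} not in normalized matrix")
    fc = np.log2(norm[treated_sample] / norm[control_sample])
    fc.name = "fc"
    return fc


def empirical_bayes_sd(fc: pd.Series, control_readcount: pd.Series, *,
                       half_window: int = DEFAULT_HALF_WINDOW) -> pd.Series:
    """Abundance-dependent spread of guide fold changes.

    Guides are ranked by descending control read count; each guide's sd is
    the sample sd of fold changes in a window of 2*half_window neighbours
    (clipped at the ends, so with fewer than 2*half_window guides every
    window is the full set). A running maximum from the abundant end
    enforces that the estimate never decreases toward low abundance.
    """
    if len(fc) < 2:
        raise ValueError("need at least 2 guides")
    df = pd.DataFrame({"fc": fc, "rc": control_readcount})
    # descending readcount; guide-id tiebreak for determinism
    order = np.lexsort((df.index.to_numpy().astype(str), -df["rc"].to_numpy()))
    df = df.iloc[order]
    x = df["fc"].to_numpy()
    n = x.size
    hw = int(half_window)
    # windowed sd via prefix sums: window [max(0,i-hw), min(n,i+hw))
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    lo = np.maximum(np.arange(n) - hw, 0)
    hi = np.minimum(np.arange(n) + hw, n)
    m = (hi - lo).astype(float)
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    var = np.maximum(s2 - s1 * s1 / m, 0.0) / np.maximum(m - 1.0, 1.0)
    sd = np.sqrt(var)
    floored = sd < _SD_FLOOR
    if floored.any():
        warnings.warn(f"{int(floored.sum())} guide sd estimates floored at "
                      f"{_SD_FLOOR}")
        sd = np.maximum(sd, _SD_FLOOR)
    sd = np.maximum.accumulate(sd)  # non-decreasing toward low abundance
    return pd.Series(sd, index=df.index, name="eb_sd").reindex(fc.index)


def guide_z(norm: pd.DataFrame, treated_sample: str, control_sample: str, *,
            half_window: int = DEFAULT_HALF_WINDOW) -> pd.DataFrame:
    """Fold change, EB sd and Z for one treated/control sample pair."""
    fc = guide_fold_changes(norm, treated_sample, control_sample)
    sd = empirical_bayes_sd(fc, norm[control_sample], half_window=half_window)
    return pd.DataFrame({"control_readcount": norm[control_sample],
                         "fc": fc, "eb_sd": sd, "z": fc / sd})


def gene_scores(guide_obs: pd.DataFrame, *, eps: float = 1e-12) -> pd.DataFrame:
    """Aggregate guide x replicate Z observations into gene-level scores.

    Input: a long DataFrame with columns ``gene`` and ``z`` (one row per
    observation). Output (indexed by gene, sorted by normZ): n_obs, sumZ,
    normZ (sumZ/sqrt(n_obs) standardized across genes by median and a
    MAD-derived scale), directional p-values and per-direction BH FDRs,
    and rank (1 = most depleted; gene-id tiebreak).
    """
    if guide_obs.empty:
        raise ValueError("no guide observations")
    grp = guide_obs.groupby("gene")["z"]
    sumz = grp.sum()
    n_obs = grp.count()
    raw = sumz / np.sqrt(n_obs)
    center = raw.median()
    mad = (raw - center).abs().median()
    scale = mad * _MAD_TO_SD
    if scale < eps:
        scale = 1.0  # degenerate spread: all scores identical
    normz = (raw - center) / scale
    p_depl = stats.norm.cdf(normz)
    p_enr = stats.norm.sf(normz)
    fdr_depl = multipletests(p_depl, method="fdr_bh")[1]
    fdr_enr = multipletests(p_enr, method="fdr_bh")[1]
    out = pd.DataFrame({"n_obs": n_obs, "sumZ": sumz, "normZ": normz,
                        "p_depletion": p_depl, "fdr_depletion": fdr_depl,
                        "p_enrichment": p_enr, "fdr_enrichment": fdr_enr})
    order = np.lexsort((out.index.to_numpy().astype(str),
                        out["normZ"].to_numpy()))
    out = out.iloc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def score_contrast(m: CountMatrix, *, treated_ph: float, control_ph: float,
                   timepoint: str = "T11",
                   pseudocount: int = DEFAULT_PSEUDOCOUNT,
                   scale: float = DEFAULT_SCALE,
                   half_window: int = DEFAULT_HALF_WINDOW) -> pd.DataFrame:
    """Full scoring of one pH contrast (e.g. 6.63 vs 7.4 at T11).

    Fold changes and Z are computed within each replicate pair and pooled
    at the guide-observation level before gene aggregation. Any other
    timepoints present (e.g. a day-5 passage sample) are ignored.
    """
    norm = normalize_counts(m, pseudocount=pseudocount, scale=scale)
    reps = sorted(set(m.meta.loc[m.samples_for(timepoint=timepoint,
                                               ph=treated_ph), "replicate"]))
    if not reps:
        raise ValueError(f"no {timepoint} samples at pH {treated_ph}")
    obs = []
    for rep in reps:
        treated = m.samples_for(timepoint=timepoint, ph=treated_ph,
                                replicate=rep)
        control = m.samples_for(timepoint=timepoint, ph=control_ph,
                                replicate=rep)
        if len(treated) != 1 or len(control) != 1:
            raise ValueError(f"replicate {rep}: expected one treated and one "
                             "control sample")
        gz = guide_z(norm, treated[0], control[0], half_window=half_window)
        gz["gene"] = m.counts["gene"]
        gz["replicate"] = rep
        obs.append(gz)
    return gene_scores(pd.concat(obs)[["gene", "z"]])


@dataclass(frozen=True)
class HitSet:
    """Genes passing a directional FDR threshold."""

    direction: str                  # "depleted" or "enriched"
    fdr_threshold: float
    genes: frozenset
    boundary_normZ: float | None    # normZ of the last gene inside the threshold

    def __len__(self) -> int:
        return len(self.genes)


def call_hits(scores: pd.DataFrame, direction: str,
              fdr_threshold: float = DEFAULT_FDR) -> HitSet:
    """Call depleted or enriched hits at a directional FDR threshold.

    ``boundary_normZ`` is the least extreme normZ among the hits — the
    data-derived analogue of a screen's Z cutoff at the chosen FDR.
    """
    if direction not in ("depleted", "enriched"):
        raise ValueError("direction must be 'depleted' or 'enriched'")
    col = "fdr_depletion" if direction == "depleted" else "fdr_enrichment"
    sub = scores[scores[col] < fdr_threshold]
    if len(sub) == 0:
        boundary = None
    elif direction == "depleted":
        boundary = float(sub["normZ"].max())
    else:
        boundary = float(sub["normZ"].min())
    return HitSet(direction=direction, fdr_threshold=fdr_threshold,
                  genes=frozenset(sub.index), boundary_normZ=boundary)


def set_overlap(a: HitSet, b: HitSet):
    """Venn partition of two hit sets of the same direction.

    Returns ((n_only_a, n_both, n_only_b), (only_a, both, only_b)).
    """
    if a.direction != b.direction:
        raise ValueError("hit sets have different directions")
    both = a.genes & b.genes
    only_a = a.genes - b.genes
    only_b = b.genes - a.genes
    return (len(only_a), len(both), len(only_b)), (only_a, both, only_b)


def _overrep_pvalue(overlap, set_size, hits, universe):
    """One-sided overrepresentation p-value: P(K >= overlap) for
    K ~ Hypergeometric(universe, set_size, hits). Identical to one-sided
    Fisher's exact on the 2x2 table. Vectorized."""
    return stats.hypergeom.sf(np.asarray(overlap) - 1, universe, set_size,
                              hits)


def overrepresentation(hits, gene_sets: dict, universe) -> pd.DataFrame:
    """Gene-set overrepresentation among hits by Fisher's exact test.

    Each set is first intersected with the universe; p-values are one-sided
    (overrepresentation) with BH correction across sets.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = frozenset(hits)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        members = frozenset(gene_sets[name]) & universe
        k = len(members & hits)
        rows.append({"set_name": name, "overlap": k,
                     "set_size": len(members), "hits": len(hits),
                     "universe": len(universe),
                     "p": float(_overrep_pvalue(k, len(members), len(hits),
                                                len(universe)))})
    table = pd.DataFrame(rows).set_index("set_name")
    table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    return table.sort_values(["p", "set_name"], kind="mergesort")


def read_gmt(path) -> dict[str, set]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
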