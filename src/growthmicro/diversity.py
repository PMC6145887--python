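"""Count-table I/O, rarefaction, alpha/beta diversity and group comparisons.

Counts are held as a samples x taxa integer matrix with a taxonomy map from
each genus-level taxon to its rank-prefixed lineage (at minimum the phylum).
Diversity summaries follow the usual definitions on relative abundances
``p_i``: Simpson concentration ``D = sum p_i^2``, inverse Simpson ``1/D`` and
Shannon entropy ``-sum p_i ln p_i`` (with ``0 ln 0 := 0``), computed by
default after aggregating counts to the phylum level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from .errors import (
    ConfigurationError,
    FormatError,
    InvalidArgumentError,
    UndefinedDiversityError,
)
from .trees import GENUS_PREFIX, PHYLUM_PREFIX, TaxTree

log = logging.getLogger(__name__)

FIRMICUTES = "Firmicutes"
BACTEROIDETES = "Bacteroidetes"


@dataclass
class AbundanceTable:
    """Samples x taxa integer counts with a taxonomy map and optional tree."""

    counts: pd.DataFrame  # index: sample ids, columns: taxon ids, int dtype
    taxonomy: dict[str, tuple[str, ...]] = field(default_factory=dict)
    tree: TaxTree | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise FormatError("abundance table must have at least one sample and one taxon")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate taxon columns: {dupes}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")

    @classmethod
    def from_tree(cls, counts: pd.DataFrame, tree: TaxTree, **kw) -> "AbundanceTable":
        return cls(counts=counts, taxonomy=tree.taxonomy(), tree=tree, **kw)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def phylum_of(self, taxon: str) -> str:
        lineage = self.taxonomy.get(taxon, ())
        for part in lineage:
            if part.startswith(PHYLUM_PREFIX):
                return part[len(PHYLUM_PREFIX):]
        raise ConfigurationError(f"taxon {taxon!r} has no phylum in its taxonomy")

    def aggregate(self, level: str = "phylum") -> pd.DataFrame:
        """Sum counts to ``level`` (only 'phylum' and 'genus' supported)."""
        if level == "genus":
            return self.counts.copy()
        if level != "phylum":
            raise InvalidArgumentError(f"unsupported aggregation level {level!r}")
        groups = {t: self.phylum_of(t) for t in self.taxon_ids}
        return self.counts.T.groupby(groups).sum().T


def read_counts(path) -> AbundanceTable:
    """Read a counts TSV: first column sample id, header of taxon names.

    Column headers may be semicolon-delimited rank-prefixed lineage strings
    (e.g. ``p__Firmicutes;g__g001``), in which case taxonomy is parsed from
    them and the taxon id is the genus segment.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate taxon columns {dupes}")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index.name = None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty abundance table")
    taxonomy: dict[str, tuple[str, ...]] = {}
    new_cols = []
    for col in raw.columns:
        if ";" in str(col):
            lineage = tuple(p.strip() for p in str(col).split(";"))
            last = lineage[-1]
            taxon = last[len(GENUS_PREFIX):] if last.startswith(GENUS_PREFIX) else last
            taxonomy[taxon] = lineage
            new_cols.append(taxon)
        else:
            new_cols.append(str(col))
    raw.columns = new_cols
    if raw.columns.duplicated().any():
        dupes = raw.columns[raw.columns.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate taxon columns {dupes}")
    for col in raw.columns:
        series = raw[col]
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = series.index[bad.argmax()]
            raise FormatError(f"{path}: non-integer count at row {row!r}, column {col!r}")
    return AbundanceTable(counts=raw.astype(np.int64), taxonomy=taxonomy)


def write_counts(table: AbundanceTable, path) -> None:
    out = table.counts.copy()
    if table.taxonomy:
        out.columns = [
            ";".join(table.taxonomy.get(t, (GENUS_PREFIX + t,))) for t in out.columns
        ]
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample's reads uniformly without replacement to ``depth``.

    Samples whose total is below ``depth`` are dropped with a logged warning
    (recorded in ``meta['rarefaction_dropped']``).
    """
    if depth <= 0:
        raise InvalidArgumentError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(np.random.SeedSequence([809180, int(seed)]))
    totals = table.counts.sum(axis=1)
    dropped = totals.index[totals < depth].tolist()
    if dropped:
        log.warning("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    kept = table.counts.loc[totals >= depth]
    out = np.empty(kept.shape, dtype=np.int64)
    for i, (_, row) in enumerate(kept.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    counts = pd.DataFrame(out, index=kept.index, columns=kept.columns)
    meta = dict(table.meta)
    meta["rarefaction_dropped"] = dropped
    meta["rarefaction_depth"] = int(depth)
    return AbundanceTable(counts=counts, taxonomy=dict(table.taxonomy),
                          tree=table.tree, meta=meta)


def _proportions(counts: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    arr = counts.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = counts.index[zero].tolist()
        raise UndefinedDiversityError(f"all-zero samples have undefined diversity: {bad}")
    return arr / totals[:, None], counts.index


def alpha_diversity(table: AbundanceTable, level: str = "phylum") -> pd.DataFrame:
    """Simpson, inverse Simpson and Shannon diversity per sample."""
    p, index = _proportions(table.aggregate(level))
    simpson = (p ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    shannon = -(p * logp).sum(axis=1)
    return pd.DataFrame(
        {
            "inverse_simpson": 1.0 / simpson,
            "shannon": shannon,
            "simpson": simpson,
        },
        index=index,
    )


def fb_ratio(table: AbundanceTable) -> pd.Series:
    """Firmicutes:Bacteroidetes read-count ratio per sample.

    Samples with zero Bacteroidetes reads get NaN (undefined, not infinite)
    and are listed in ``table.meta['fb_undefined']``.
    """
    phyla = table.aggregate("phylum")
    for needed in (FIRMICUTES, BACTEROIDETES):
        if needed not in phyla.columns:
            raise ConfigurationError(
                f"phylum {needed!r} absent from taxonomy; cannot form F:B ratio"
            )
    firm = phyla[FIRMICUTES].to_numpy(dtype=float)
    bact = phyla[BACTEROIDETES].to_numpy(dtype=float)
    ratio = np.full_like(firm, np.nan)
    ok = bact > 0
    ratio[ok] = firm[ok] / bact[ok]
    undefined = phyla.index[~ok].tolist()
    if undefined:
        log.warning("fb_ratio undefined (zero Bacteroidetes) for samples: %s", undefined)
    table.meta["fb_undefined"] = undefined
    return pd.Series(ratio, index=phyla.index, name="fb_ratio")


def diversity_summary(table: AbundanceTable, level: str = "phylum") -> pd.DataFrame:
    """Alpha diversity measures plus the F:B ratio, per sample."""
    out = alpha_diversity(table, level=level)
    out["fb_ratio"] = fb_ratio(table)
    return out


def phylum_proportion_tests(tables_by_group: dict[str, AbundanceTable],
                            phyla: list[str] | None = None,
                            m_tests: int | None = None) -> pd.DataFrame:
    """Chi-squared tests of phylum proportions between groups of samples.

    For each phylum and group, "successes" are the mean within-sample
    proportion times the group size (rounded to the nearest integer) and
    "failures" the remainder; a Pearson chi-squared test is applied to the
    groups x {success, failure} table.  Yates continuity correction is used
    for two-group comparisons only.  P-values are Bonferroni-multiplied by
    ``m_tests`` (default: the number of tests performed) and capped at 1.
    """
    if len(tables_by_group) < 2:
        raise InvalidArgumentError("need at least two groups")
    for name, tab in tables_by_group.items():
        if tab.counts.shape[0] == 0:
            raise InvalidArgumentError(f"group {name!r} has no samples")
    group_props = {}
    for name, tab in tables_by_group.items():
        phy = tab.aggregate("phylum")
        p, _ = _proportions(phy)
        group_props[name] = pd.DataFrame(p, columns=phy.columns)
    if phyla is None:
        phyla = sorted(set().union(*(gp.columns for gp in group_props.values())))
    if m_tests is None:
        m_tests = len(phyla)
    rows = []
    names = list(group_props)
    for phylum in phyla:
        contingency = []
        for name in names:
            gp = group_props[name]
            n_g = gp.shape[0]
            mean_prop = float(gp[phylum].mean()) if phylum in gp.columns else 0.0
            successes = int(round(mean_prop * n_g))
            contingency.append([successes, n_g - successes])
        contingency = np.asarray(contingency)
        if contingency[:, 0].sum() == 0 or contingency[:, 1].sum() == 0:
            stat, p_raw = 0.0, 1.0
        else:
            correction = len(names) == 2
            stat, p_raw, _, _ = stats.chi2_contingency(contingency, correction=correction)
        rows.append(
            {
                "phylum": phylum,
                "groups": "|".join(names),
                "chi2": float(stat),
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(1.0, p_raw * m_tests)),
            }
        )
    return pd.DataFrame(rows)


def mw_one_tailed(values_a, values_b, direction: str) -> float:
    """One-tailed Mann-Whitney U p-value for group a vs group b.

    ``direction`` is the alternative for group a relative to group b
    ("less" or "greater"); there is deliberately no two-sided default.
    Small tie-free samples use the exact U distribution, otherwise the
    normal approximation with tie correction.
    """
    if direction not in ("less", "greater"):
        raise InvalidArgumentError(
            f"direction must be 'less' or 'greater', got {direction!r}"
        )
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each group needs at least two finite values")
    res = stats.mannwhitneyu(a, b, alternative=direction, method="auto",
                             use_continuity=False)
    return float(res.pvalue)


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity ``sum|a-b| / sum(a+b)`` between all samples.

    Pairs with zero total counts are undefined (NaN) and flagged in
    ``table.meta['bray_curtis_undefined_pairs']``.
    """
    arr = table.counts.to_numpy(dtype=float)
    n = arr.shape[0]
    diffs = np.abs(arr[:, None, :] - arr[None, :, :]).sum(axis=2)
    sums = (arr[:, None, :] + arr[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(sums > 0, diffs / np.where(sums > 0, sums, 1.0), np.nan)
    np.fill_diagonal(d, 0.0)
    undefined = [
        (table.counts.index[i], table.counts.index[j])
        for i in range(n) for j in range(i + 1, n)
        if not np.isfinite(d[i, j])
    ]
    if undefined:
        log.warning("bray_curtis undefined for %d zero-sum pairs", len(undefined))
    table.meta["bray_curtis_undefined_pairs"] = undefined
    return pd.DataFrame(d, index=table.counts.index, columns=table.counts.index)


def condensed(dissimilarity: pd.DataFrame) -> np.ndarray:
    """Condensed upper-triangle form of a square dissimilarity matrix."""
    return squareform(dissimilarity.to_numpy(), checks=False)
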