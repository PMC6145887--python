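"""Synthetic mother-child cohort generator with known ground truth.

Emulates the data layout of a longitudinal infant-growth / microbiome study:
sparse weight and length measurements at seven clinic visits over the first
two years, genus-level 16S count tables with phylogenetically clustered
sparsity and collinearity, an LMS-style growth reference, and a covariate
table with categorical co-factors plus weekly diet frequencies (two of which
are built collinear so pruning has work to do).  Growth-index trajectories
follow a low-rank functional model ``mu(t) + sum_k xi_ik phi_k(t) +
sum_j x_ij beta_j(t)`` with configurable microbiota effects, and the exact
generating quantities are returned as :class:`SyntheticTruth` so downstream
estimators can be checked for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .anthro import AnthroRecord, GrowthReference, Visit
from .covariates import CovariateTable, DIET_COLUMNS, FACTOR_COLUMNS
from .diversity import AbundanceTable, diversity_summary
from .errors import InvalidArgumentError
from .fosr import trapezoid_weights
from .trees import TaxTree

PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")

#: birth, 3-4 weeks, 16 weeks, 28 weeks, 40 weeks, 1 year, 2 years (days)
DEFAULT_VISIT_AGES = (0, 25, 112, 196, 280, 365, 730)

# multinomial count model: per-sample log-normal jitter of base proportions,
# plus a shared latent factor for designated sibling pairs
_GENUS_LOGNOISE_SD = 0.3
_SHARED_FACTOR_SD = 1.0
_RARE_BASE_PER_DEPTH = 1.0     # expected count of a rare genus per sample
_COMMON_FLOOR_PER_DEPTH = 20.0
_CORR_FLOOR_PROPORTION = 0.015  # keep correlated pairs well above Poisson noise

EFFECT_SHAPES = {
    "constant": lambda u: np.ones_like(u),
    "linear": lambda u: u,
    "sin": lambda u: np.sin(np.pi * u),
    "bump": lambda u: np.exp(-0.5 * ((u - 0.5) / 0.15) ** 2),
}


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(salt), int(seed)]))


@dataclass
class SyntheticConfig:
    """Stated world for the synthetic cohort."""

    n_children: int = 200
    n_genera: int = 75
    visit_ages: tuple[int, ...] = DEFAULT_VISIT_AGES
    missing_rate: float = 0.1
    effect_map: tuple = (
        ("oral_inverse_simpson", "sin", -0.003),
        ("oral_fb_ratio", "sin", 0.003),
    )
    noise_sd: float = 0.004          # growth-index units (kg/cm)
    seed: int = 0
    # extras with defaults (not part of the minimal surface)
    pc_sds: tuple[float, ...] = (0.008, 0.004)
    pc_shapes: tuple[str, ...] = ("poly0", "poly1")
    age_jitter_days: int = 7        # non-birth visits drift around the schedule
    length_noise_sd: float = 0.004  # per-visit relative length measurement error
    depth: int = 100_000
    sparsity_frac: float = 0.4
    n_corr_pairs: int = 1

    def __post_init__(self):
        if self.n_children < 10:
            raise InvalidArgumentError("n_children must be >= 10")
        ages = tuple(self.visit_ages)
        if ages[0] != 0 or any(b <= a for a, b in zip(ages, ages[1:])):
            raise InvalidArgumentError(
                "visit_ages must be strictly increasing with first age 0"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidArgumentError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Exact generating quantities for parameter-recovery tests."""

    grid: np.ndarray
    mean: np.ndarray
    eigenfunctions: np.ndarray     # (K, T), orthonormal on the grid
    eigenvalues: np.ndarray        # (K,), nonincreasing
    scores: np.ndarray             # (n, K)
    curves: np.ndarray             # (n, T) true latent growth-index curves
    effects: dict                  # predictor name -> true effect curve on grid
    design: pd.DataFrame           # standardized predictors actually used
    corr_blocks: list = field(default_factory=list)


# --------------------------------------------------------------------------
# tree
# --------------------------------------------------------------------------

def gen_tree(n_genera: int, seed: int) -> TaxTree:
    """Random rooted bifurcating taxonomy tree over ``n_genera`` genus leaves.

    Leaves are partitioned into phyla (including Firmicutes and
    Bacteroidetes) whose subtree roots carry ``p__`` labels, so phylum
    membership is recoverable for every leaf.
    """
    if n_genera < 4:
        raise InvalidArgumentError("need at least 4 genera")
    rng = _rng(seed, 1001)
    n_phyla = 2 if n_genera < 8 else 4
    sizes = np.full(n_phyla, 2)
    extra = rng.multinomial(n_genera - 2 * n_phyla, np.full(n_phyla, 1.0 / n_phyla))
    sizes = sizes + extra
    leaf_names = [f"g{i + 1:03d}" for i in range(n_genera)]
    counter = [0]

    def namer():
        counter[0] += 1
        return f"n{counter[0]}"

    def random_join(nodes, top_name):
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(int(j))
            a = nodes.pop(int(i))
            name = top_name if len(nodes) == 0 else namer()
            parent = TreeNode(name=name, length=1.0)
            parent.extend([a, b])
            nodes.append(parent)
        nodes[0].name = top_name
        return nodes[0]

    subtrees = []
    start = 0
    for phylum, size in zip(PHYLA[:n_phyla], sizes):
        leaves = [TreeNode(name=nm, length=1.0)
                  for nm in leaf_names[start:start + size]]
        start += size
        subtrees.append(random_join(leaves, f"p__{phylum}"))
    root = random_join(subtrees, "root")
    root.length = None
    return TaxTree(root)


# --------------------------------------------------------------------------
# abundances
# --------------------------------------------------------------------------

def sibling_leaf_pairs(tree: TaxTree) -> list[tuple[str, str]]:
    """All (leaf, leaf) sibling pairs, in tree order."""
    pairs = []
    for node in tree.root.traverse(include_self=True):
        if node.is_tip():
            continue
        tips = [c for c in node.children if c.is_tip()]
        for a, b in zip(tips, tips[1:]):
            pairs.append((a.name, b.name))
    return pairs


def gen_abundances(tree: TaxTree, n_samples: int, depth: int,
                   sparsity_frac: float, corr_blocks, seed: int) -> AbundanceTable:
    """Multinomial genus counts with planted rarity and sibling correlation.

    A fraction ``sparsity_frac`` of genera get base proportions of about one
    read per sample (rare by the <5-counts-in->90%-of-samples rule); members
    of each ``corr_blocks`` sibling pair share a latent log-normal factor so
    their counts are strongly correlated.
    """
    if depth < 1000:
        raise InvalidArgumentError("depth must be >= 1000")
    if not 0.0 <= sparsity_frac < 1.0:
        raise InvalidArgumentError("sparsity_frac must be in [0, 1)")
    leaves = tree.leaf_names
    n_genera = len(leaves)
    index = {nm: i for i, nm in enumerate(leaves)}
    for a, b in corr_blocks:
        na, nb = tree.find(a), tree.find(b)
        if not (na.is_tip() and nb.is_tip() and na.parent is nb.parent):
            raise InvalidArgumentError(
                f"corr_blocks entries must be sibling leaves, got ({a!r}, {b!r})"
            )
    rng = _rng(seed, 1002)
    protected = {nm for pair in corr_blocks for nm in pair}
    # keep one abundant anchor genus per phylum so phylum-level summaries
    # (e.g. the F:B ratio) stay well-defined in every sample
    anchors = {}
    for nm in leaves:
        anchors.setdefault(tree.phylum_of(nm), nm)
    protected |= set(anchors.values())
    eligible = [nm for nm in leaves if nm not in protected]
    n_rare = int(round(sparsity_frac * n_genera))
    if n_rare > len(eligible):
        raise InvalidArgumentError("sparsity_frac too high given corr_blocks")
    rare = set(rng.choice(eligible, size=n_rare, replace=False)) if n_rare else set()

    base = np.empty(n_genera)
    common = [nm for nm in leaves if nm not in rare]
    raw = np.maximum(rng.lognormal(0.0, 1.0, size=len(common)),
                     _COMMON_FLOOR_PER_DEPTH / depth)
    raw = raw / raw.sum() * (1.0 - n_rare * _RARE_BASE_PER_DEPTH / depth)
    for nm, v in zip(common, raw):
        base[index[nm]] = v
    for nm in protected:
        base[index[nm]] = max(base[index[nm]], _CORR_FLOOR_PROPORTION)
    for nm in rare:
        base[index[nm]] = _RARE_BASE_PER_DEPTH / depth

    counts = np.empty((n_samples, n_genera), dtype=np.int64)
    for s in range(n_samples):
        logw = np.log(base) + rng.normal(0.0, _GENUS_LOGNOISE_SD, size=n_genera)
        for a, b in corr_blocks:
            shared = rng.normal(0.0, _SHARED_FACTOR_SD)
            logw[index[a]] += shared
            logw[index[b]] += shared
        w = np.exp(logw)
        counts[s] = rng.multinomial(depth, w / w.sum())
    frame = pd.DataFrame(counts, columns=leaves,
                         index=[f"S{s + 1:04d}" for s in range(n_samples)])
    table = AbundanceTable.from_tree(frame, tree)
    table.meta["planted_rare"] = sorted(rare)
    table.meta["planted_corr_blocks"] = [tuple(p) for p in corr_blocks]
    return table


# --------------------------------------------------------------------------
# growth reference
# --------------------------------------------------------------------------

def gen_reference(visit_ages) -> GrowthReference:
    """Smooth LMS reference tables (weight and length, both sexes, daily grid).

    A stand-in for an external growth standard: median curves rise
    monotonically from realistic birth sizes to realistic two-year sizes,
    S lies in (0, 0.3) and L in [-2, 2].
    """
    ages = np.asarray(sorted(visit_ages), dtype=float)
    if ages[0] > 0 or ages[-1] < 730:
        raise InvalidArgumentError("visit ages must cover [0, 730] days")
    grid = np.arange(0, 731, dtype=float)
    u = grid / 730.0
    rows = []
    median = {
        ("male", "weight"): 3.35 + (12.2 - 3.35) * u ** 0.55,
        ("female", "weight"): 3.23 + (11.5 - 3.23) * u ** 0.55,
        ("male", "length"): 49.9 + (87.8 - 49.9) * u ** 0.65,
        ("female", "length"): 49.1 + (86.4 - 49.1) * u ** 0.65,
    }
    for (sex, measure), M in median.items():
        if measure == "weight":
            L = 0.25 - 0.10 * u
            S = 0.11 + 0.02 * u
        else:
            L = np.ones_like(u)
            S = np.full_like(u, 0.035)
        for a, l, m, s in zip(grid, L, M, S):
            rows.append({"sex": sex, "measure": measure, "age_days": a,
                         "L": l, "M": m, "S": s})
    return GrowthReference(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# covariates
# --------------------------------------------------------------------------

def gen_covariates(n_children: int, seed: int) -> CovariateTable:
    """Nine categorical/binary co-factors plus ten weekly diet frequencies.

    'milk' is built collinear with 'dairy' and 'vegetables_no_potato' with
    'vegetables' (|r| > 0.7), so correlation pruning has work to do.
    """
    if n_children < 10:
        raise InvalidArgumentError("n_children must be >= 10")
    rng = _rng(seed, 1003)
    n = n_children
    frame = pd.DataFrame(index=pd.Index([f"c{i:04d}" for i in range(n)],
                                        name="child_id"))
    frame["sex"] = rng.choice(["male", "female"], size=n)
    frame["antibiotics"] = rng.choice(["no", "yes"], size=n, p=[0.65, 0.35])
    frame["acid_reducers"] = rng.choice(["no", "yes"], size=n, p=[0.85, 0.15])
    frame["delivery_mode"] = rng.choice(["vaginal", "cesarean"], size=n, p=[0.7, 0.3])
    frame["intervention"] = rng.choice(["control", "responsive"], size=n)
    frame["gestational_diabetes"] = rng.choice(["no", "yes"], size=n, p=[0.9, 0.1])
    frame["gestational_weight_gain"] = rng.choice(
        ["low", "normal", "high"], size=n, p=[0.2, 0.5, 0.3])
    frame["smoking"] = rng.choice(["no", "yes"], size=n, p=[0.88, 0.12])
    frame["income"] = rng.choice(
        ["<25k", "25-50k", "50-75k", "75-100k", ">100k"], size=n,
        p=[0.08, 0.17, 0.3, 0.25, 0.2])

    clip42 = lambda x: np.clip(np.rint(x), 0, 42).astype(int)
    dairy = rng.poisson(9.0, size=n)
    vegetables = rng.poisson(11.0, size=n)
    frame["sugar_sweetened_beverages"] = clip42(rng.poisson(3.0, size=n))
    frame["milk"] = clip42(0.85 * dairy + rng.normal(0.0, 1.2, size=n))
    frame["dairy"] = clip42(dairy)
    frame["fruit"] = clip42(rng.poisson(10.0, size=n))
    frame["vegetables"] = clip42(vegetables)
    frame["vegetables_no_potato"] = clip42(
        0.9 * vegetables + rng.normal(0.0, 1.1, size=n))
    frame["snacks"] = clip42(rng.poisson(7.0, size=n))
    frame["sweets"] = clip42(rng.poisson(5.0, size=n))
    frame["meats"] = clip42(rng.poisson(6.0, size=n))
    frame["fried_foods"] = clip42(rng.poisson(2.0, size=n))
    return CovariateTable(frame=frame, factor_columns=list(FACTOR_COLUMNS),
                          diet_columns=list(DIET_COLUMNS))


# --------------------------------------------------------------------------
# growth trajectories
# --------------------------------------------------------------------------

_PC_SHAPES = {
    "poly0": lambda u: np.ones_like(u),
    "poly1": lambda u: u,
    "poly2": lambda u: u ** 2,
    "sin1": lambda u: np.sin(np.pi * u),
    "sin2": lambda u: np.sin(2.0 * np.pi * u),
    "cos1": lambda u: np.cos(np.pi * u),
}


def _orthonormal_components(grid: np.ndarray, shapes) -> np.ndarray:
    """Gram-Schmidt of the named shape functions under trapezoid quadrature."""
    u = (grid - grid[0]) / (grid[-1] - grid[0])
    w = trapezoid_weights(grid)
    phis = []
    for shape in shapes:
        v = np.asarray(_PC_SHAPES[shape](u), dtype=float)
        for p in phis:
            v = v - (v @ (w * p)) * p
        v = v / np.sqrt(v @ (w * v))
        phis.append(v)
    return np.vstack(phis)


def true_mean_curve(grid: np.ndarray) -> np.ndarray:
    """Monotone weight-for-length index curve, ~0.067 at birth to ~0.14 at 2y."""
    u = (grid - grid[0]) / (grid[-1] - grid[0])
    return 0.067 + 0.073 * u ** 0.7


def gen_growth(config: SyntheticConfig, abundance_features: pd.DataFrame | None
               ) -> tuple[list[AnthroRecord], SyntheticTruth]:
    """Sparse anthropometry records plus the exact generating truth.

    Child i's latent growth-index curve is ``mu + sum_k xi_ik phi_k +
    sum_j x_ij beta_j``; the index is observed at non-missing visits with
    i.i.d. Gaussian noise, lengths follow the reference median with
    child-level variation, and weights are back-solved so that
    weight/length equals the noisy index exactly.  The birth visit is never
    missing.
    """
    n = config.n_children
    effects = list(config.effect_map)
    if effects:
        if abundance_features is None:
            raise InvalidArgumentError("effect_map given but abundance_features is None")
        if abundance_features.shape[0] != n:
            raise InvalidArgumentError(
                f"abundance_features has {abundance_features.shape[0]} rows, "
                f"expected n_children = {n}"
            )
        unknown = [nm for nm, _, _ in effects
                   if nm not in abundance_features.columns]
        if unknown:
            raise InvalidArgumentError(f"effect_map names unknown predictors {unknown}")

    rng = _rng(config.seed, 1004)
    grid = np.arange(0, 731, dtype=float)
    u = grid / 730.0
    mu = true_mean_curve(grid)
    K = len(config.pc_sds)
    if len(config.pc_shapes) != K:
        raise InvalidArgumentError("pc_shapes and pc_sds must have equal length")
    phis = _orthonormal_components(grid, config.pc_shapes)
    # pc_sds are typical per-child curve deviations in index units; since the
    # eigenfunctions are orthonormal over the day-scale domain (amplitude
    # ~ 1/sqrt(span)), the score variances carry the span factor
    span = grid[-1] - grid[0]
    lams = (np.asarray(config.pc_sds, dtype=float) * np.sqrt(span)) ** 2
    order = np.argsort(lams)[::-1]
    lams, phis = lams[order], phis[order]
    scores = rng.normal(0.0, np.sqrt(lams)[None, :], size=(n, K))

    effect_curves: dict[str, np.ndarray] = {}
    design = pd.DataFrame(index=(abundance_features.index
                                 if abundance_features is not None
                                 else pd.RangeIndex(n)))
    signal = np.zeros((n, grid.size))
    for name, shape, amplitude in effects:
        fn = EFFECT_SHAPES[shape] if isinstance(shape, str) else shape
        beta = float(amplitude) * np.asarray(fn(u), dtype=float)
        effect_curves[name] = beta
        x = abundance_features[name].to_numpy(dtype=float)
        sd = x.std()
        x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        design[name] = x
        signal += np.outer(x, beta)

    curves = mu[None, :] + scores @ phis + signal

    reference = gen_reference(config.visit_ages)
    sexes = rng.choice(["male", "female"], size=n)
    delta = rng.normal(0.0, 0.02, size=n)   # child-level length multiplier
    ages = np.asarray(config.visit_ages, dtype=int)
    records = []
    ids = [f"c{i:04d}" for i in range(n)]
    jit = config.age_jitter_days
    for i in range(n):
        keep = np.ones(ages.size, dtype=bool)
        keep[1:] = rng.random(ages.size - 1) >= config.missing_rate
        obs_ages = ages.copy()
        if jit > 0:
            obs_ages[1:] = np.clip(
                ages[1:] + rng.integers(-jit, jit + 1, size=ages.size - 1),
                1, 730)
        visits = []
        for a in obs_ages[keep]:
            idx_val = curves[i, a] + rng.normal(0.0, config.noise_sd)
            _, m_len, _ = reference.lms(sexes[i], "length", float(a))
            length = m_len * (1.0 + delta[i]) * (
                1.0 + rng.normal(0.0, config.length_noise_sd))
            visits.append(Visit(int(a), float(idx_val * length), float(length)))
        records.append(AnthroRecord(ids[i], sexes[i], visits))

    truth = SyntheticTruth(
        grid=grid, mean=mu, eigenfunctions=phis, eigenvalues=lams,
        scores=scores, curves=curves, effects=effect_curves, design=design,
    )
    return records, truth


# --------------------------------------------------------------------------
# whole cohort
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    tree: TaxTree
    tables: dict[str, AbundanceTable]      # site -> counts (oral, gut)
    features: pd.DataFrame                 # per-child diversity summaries
    records: list[AnthroRecord]
    reference: GrowthReference
    covariates: CovariateTable
    truth: SyntheticTruth

    def write(self, outdir) -> dict[str, str]:
        from pathlib import Path

        from .anthro import write_anthropometry
        from .diversity import write_counts

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        self.tree.write(outdir / "tree.nwk")
        paths["tree"] = str(outdir / "tree.nwk")
        for site, table in self.tables.items():
            p = outdir / f"counts_{site}.tsv"
            write_counts(table, p)
            paths[f"counts_{site}"] = str(p)
        write_anthropometry(self.records, outdir / "anthropometry.csv")
        paths["anthropometry"] = str(outdir / "anthropometry.csv")
        self.reference.write(outdir / "reference.csv")
        paths["reference"] = str(outdir / "reference.csv")
        self.covariates.write(outdir / "covariates.csv")
        paths["covariates"] = str(outdir / "covariates.csv")
        self.features.to_csv(outdir / "features.csv")
        paths["features"] = str(outdir / "features.csv")
        return paths


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate tree, oral/gut counts, anthropometry, covariates and truth."""
    tree = gen_tree(config.n_genera, config.seed)
    pairs = sibling_leaf_pairs(tree)[: config.n_corr_pairs]
    tables = {}
    feats = {}
    for k, site in enumerate(("oral", "gut")):
        table = gen_abundances(tree, config.n_children, config.depth,
                               config.sparsity_frac, pairs,
                               seed=config.seed * 7 + k)
        summ = diversity_summary(table)
        summ.index = [f"c{i:04d}" for i in range(config.n_children)]
        tables[site] = table
        feats[f"{site}_inverse_simpson"] = summ["inverse_simpson"]
        feats[f"{site}_fb_ratio"] = summ["fb_ratio"]
    features = pd.DataFrame(feats)
    # undefined summaries (e.g. F:B with zero Bacteroidetes) would poison the
    # planted effects; impute with the column median for the design only
    records, truth = gen_growth(config, features.fillna(features.median()))
    truth.corr_blocks = list(pairs)
    reference = gen_reference(config.visit_ages)
    covariates = gen_covariates(config.n_children, config.seed)
    return SyntheticCohort(config=config, tree=tree, tables=tables,
                           features=features, records=records,
                           reference=reference, covariates=covariates,
                           truth=truth)
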