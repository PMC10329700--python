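"""Synthetic p180-style targeted-metabolomics cohorts with known ground truth.

The generator emulates the structure of a brain-tumor plasma metabolomics
study: six diagnostic groups (glioma grades I-IV, meningioma, healthy
controls; default 3/15/10/66/70/71 samples, 235 in total), 188 metabolites
drawn from the p180 compound classes, three acquisition batches, lognormal
concentrations with within-class correlation, and limit-of-detection
censoring recorded per metabolite and batch.

Ground-truth group effects are planted on the log scale: univariate mean
shifts (in units of the log-scale SD) and bivariate rank reversals, where the
two metabolites' latent means are swapped in the target group so their
typical ordering flips while the marginal distributions stay similar.

A minority of metabolites (default 15%) is simulated as poorly detected,
censored at their batch median, so the 80%-presence filter retains most but
not all features — the filter has genuine work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GROUPS, MetaboliteMatrix

DEFAULT_GROUP_SIZES = {"GI": 3, "GII": 15, "GIII": 10, "GIV": 66, "MT": 70, "Con": 71}

#: default compound-class composition summing to 188 features
DEFAULT_CLASS_COUNTS = {
    "amino_acid": 21,
    "biogenic_amine": 21,
    "acylcarnitine": 40,
    "lysoPC": 14,
    "PC": 76,
    "sphingolipid": 15,
    "hexose": 1,
}

_AMINO_ACIDS = (
    "Alanine Arginine Asparagine Aspartate Citrulline Glutamine Glutamate "
    "Glycine Histidine Isoleucine Leucine Lysine Methionine Ornithine "
    "Phenylalanine Proline Serine Threonine Tryptophan Tyrosine Valine"
).split()

_BIOGENIC_AMINES = (
    "ADMA SDMA Taurine Creatinine Kynurenine Serotonin Putrescine Spermidine "
    "Spermine Sarcosine Histamine Dopamine DOPA Carnosine alpha-AAA Ac-Orn "
    "Met-SO Nitro-Tyr OH-Pro PEA total-DMA"
).split()


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Log-scale units: ``log_mean_range`` spans baseline log-concentrations
    (natural log of µM), ``log_sd`` is the biological SD on that scale, and
    effect shifts are expressed in multiples of ``log_sd``.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    n_batches: int = 3
    log_mean_range: tuple[float, float] = (-1.0, 4.0)
    log_sd: float = 0.5
    batch_sd: float = 0.1
    class_correlation: float = 0.3
    univariate_effects: list[tuple[str, str, float]] | None = None
    bivariate_effects: list[tuple[str, str, str]] | None = None
    lod_quantile: float = 0.05
    low_detect_fraction: float = 0.15
    low_detect_quantile: float = 0.50
    seed: int = 0

    @property
    def n_metabolites(self) -> int:
        return sum(self.class_counts.values())

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    def validate(self) -> None:
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if not 0 <= self.low_detect_quantile < 1:
            raise ValueError("low_detect_quantile must be in [0, 1)")
        if not 0 <= self.class_correlation < 1:
            raise ValueError("class_correlation must be in [0, 1)")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")


@dataclass
class TruthRecord:
    """What was planted, for parameter-recovery checks."""

    univariate_markers: list[tuple[str, str, float]]
    bivariate_pairs: list[tuple[str, str, str]]
    lods: pd.DataFrame
    low_detect_metabolites: list[str]
    censoring_fraction: float


def p180_feature_names(cfg: SimConfig | None = None) -> pd.DataFrame:
    """Format-faithful synthetic metabolite names with compound classes.

    Names mimic p180 kit conventions ("PC aa C42:0", "SM C24:1",
    "lysoPC a C18:0", plain amino-acid names); the per-class counts are a
    plausible default split, configurable via ``cfg.class_counts``.
    """
    cfg = cfg or SimConfig()
    rows: list[tuple[str, str]] = []

    def lipid_series(prefix: str, count: int, start_c: int = 14, sats=(0, 1, 2)):
        names = []
        c, i = start_c, 0
        while len(names) < count:
            names.append(f"{prefix} C{c}:{sats[i % len(sats)]}")
            i += 1
            if i % len(sats) == 0:
                c += 2
        return names

    for cls, count in cfg.class_counts.items():
        if cls == "amino_acid":
            base = _AMINO_ACIDS
            names = [base[i % len(base)] + ("" if i < len(base) else f"-{i // len(base)}")
                     for i in range(count)]
        elif cls == "biogenic_amine":
            base = _BIOGENIC_AMINES
            names = [base[i % len(base)] + ("" if i < len(base) else f"-{i // len(base)}")
                     for i in range(count)]
        elif cls == "acylcarnitine":
            names = []
            c, i = 0, 0
            variants = ("", ":1", "-OH")
            while len(names) < count:
                names.append(f"C{c}{variants[i % 3]}")
                i += 1
                if i % 3 == 0:
                    c += 2 if c else 2
            names = names[:count]
        elif cls == "lysoPC":
            names = lipid_series("lysoPC a", count)
        elif cls == "PC":
            half = count // 2
            names = lipid_series("PC aa", count - half, start_c=24) + lipid_series(
                "PC ae", half, start_c=30
            )
        elif cls == "sphingolipid":
            half = count // 3
            names = lipid_series("SM", count - half, start_c=16, sats=(0, 1)) + lipid_series(
                "SM (OH)", half, start_c=14
            )
        else:  # hexose / anything else
            names = [f"H{i + 1}" for i in range(count)]
        for n in names[:count]:
            rows.append((n, cls))

    df = pd.DataFrame(rows, columns=["metabolite", "compound_class"])
    if df["metabolite"].duplicated().any():
        dupes = df["metabolite"][df["metabolite"].duplicated()].tolist()
        raise ValueError(f"class counts produce duplicate names: {dupes[:5]}")
    return df


def default_effects(names: list[str], groups=GROUPS) -> tuple[list, list]:
    """Default planted effects: a realistic marker set for a tumor cohort.

    Ten univariate log-scale shifts between 0.8 and 2.0 SD spread over the
    tumor groups, and three rank-reversal pairs among well-quantified
    metabolites.
    """
    uni_spec = [
        ("Taurine", "GIV", 2.0),
        ("Aspartate", "GIV", -1.5),
        ("Asparagine", "GIV", 1.2),
        ("SM C24:1", "GIV", -1.2),
        ("Glutamate", "GIII", 1.5),
        ("Kynurenine", "GIII", 1.0),
        ("lysoPC a C18:0", "GII", -1.0),
        ("ADMA", "MT", 0.8),
        ("Alanine", "MT", 1.0),
        ("PC aa C36:0", "GIV", 0.8),
    ]
    bi_spec = [
        ("Glutamine", "Glycine", "GIV"),
        ("SM C16:0", "SM C18:1", "MT"),
        ("C2", "C4", "GIII"),
    ]
    uni = [(m, g, s) for m, g, s in uni_spec if m in names and g in groups]
    bi = [(a, b, g) for a, b, g in bi_spec if a in names and b in names and g in groups]
    return uni, bi


def simulate(cfg: SimConfig | None = None) -> tuple[MetaboliteMatrix, TruthRecord]:
    """Generate a cohort matrix with LOD-censored missingness and ground truth.

    Deterministic given ``cfg.seed``; the same configuration always yields a
    byte-identical CSV via :func:`~evohdtree.io.write_matrix`.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    feats = p180_feature_names(cfg)
    names = feats["metabolite"].tolist()
    classes = feats["compound_class"].tolist()
    name_idx = {n: i for i, n in enumerate(names)}
    p = len(names)
    n = cfg.n_samples

    groups = np.concatenate(
        [[g] * c for g, c in cfg.group_sizes.items() if c > 0]
    ) if n else np.array([], dtype=str)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    batches = np.array([f"B{(i % cfg.n_batches) + 1}" for i in rng.permutation(n)])

    uni = cfg.univariate_effects
    bi = cfg.bivariate_effects
    if uni is None and bi is None:
        uni, bi = default_effects(names, groups=set(cfg.group_sizes))
    uni = uni or []
    bi = bi or []
    for m, g, _ in uni:
        if m not in name_idx or g not in cfg.group_sizes:
            raise ValueError(f"planted univariate effect references unknown {m!r}/{g!r}")
    for a, b, g in bi:
        if a not in name_idx or b not in name_idx or g not in cfg.group_sizes:
            raise ValueError(f"planted bivariate effect references unknown {a!r}/{b!r}/{g!r}")

    lo, hi = cfg.log_mean_range
    mu = rng.uniform(lo, hi, size=p)
    # rank-reversal pairs: give the pair a clear baseline ordering (a above b
    # by 2 log-SD), then swap their latent means inside the target group
    for a, b, _g in bi:
        ia, ib = name_idx[a], name_idx[b]
        center = (mu[ia] + mu[ib]) / 2.0
        mu[ia] = center + cfg.log_sd
        mu[ib] = center - cfg.log_sd

    batch_levels = sorted(set(batches)) if n else []
    batch_offset = {
        b: rng.normal(0.0, cfg.batch_sd, size=p) for b in batch_levels
    }

    M = np.tile(mu, (n, 1))
    for met, grp, shift in uni:
        M[groups == grp, name_idx[met]] += shift * cfg.log_sd
    for a, b, grp in bi:
        ia, ib = name_idx[a], name_idx[b]
        rows = groups == grp
        M[rows, ia], M[rows, ib] = M[rows, ib].copy(), M[rows, ia].copy()

    # correlated noise: one latent factor per compound class per sample
    rho = cfg.class_correlation
    class_levels = sorted(set(classes))
    class_of = np.array([class_levels.index(c) for c in classes])
    z_class = rng.normal(size=(n, len(class_levels)))
    eps = rng.normal(size=(n, p))
    noise = np.sqrt(rho) * z_class[:, class_of] + np.sqrt(1.0 - rho) * eps
    log_x = M + cfg.log_sd * noise
    for b in batch_levels:
        log_x[batches == b] += batch_offset[b]
    x = np.exp(log_x)

    # per-(metabolite, batch) LODs from the batch marginal quantile
    n_low = int(round(cfg.low_detect_fraction * p))
    planted = {name_idx[m] for m, _, _ in uni} | {
        name_idx[c] for a, b, _ in bi for c in (a, b)
    }
    eligible = np.array([j for j in range(p) if j not in planted])
    low_detect = (
        np.sort(rng.choice(eligible, size=min(n_low, len(eligible)), replace=False))
        if n_low
        else np.array([], dtype=int)
    )
    q = np.full(p, cfg.lod_quantile)
    q[low_detect] = cfg.low_detect_quantile

    lod = pd.DataFrame(index=names, columns=batch_levels, dtype=float)
    values = x.copy()
    for b in batch_levels:
        rows = batches == b
        sub = x[rows]
        for j in range(p):
            lod_val = float(np.quantile(sub[:, j], q[j])) if rows.any() else np.nan
            lod.iat[j, batch_levels.index(b)] = lod_val
            below = rows.copy()
            below[rows] = sub[:, j] < lod_val
            values[below, j] = np.nan

    vals = pd.DataFrame(values, index=sample_ids, columns=names)
    matrix = MetaboliteMatrix(
        values=vals,
        group=pd.Series(groups, index=sample_ids, name="group"),
        batch=pd.Series(batches, index=sample_ids, name="batch"),
        lod=lod,
        metabolite_class=pd.Series(classes, index=names, name="compound_class"),
    )
    truth = TruthRecord(
        univariate_markers=list(uni),
        bivariate_pairs=list(bi),
        lods=lod,
        low_detect_metabolites=[names[j] for j in low_detect],
        censoring_fraction=float(np.isnan(values).mean()),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Small noise-free constructions used for parameter-recovery checks


def make_threshold_dataset(
    n_pos: int = 20,
    n_neg: int = 20,
    p: int = 6,
    feature: int = 0,
    threshold: float = 5.0,
    seed: int = 0,
):
    """Planted univariate rule: positives above ``threshold``, negatives below.

    Distractor features are iid standard normal in both classes, and the
    informative feature sits far above the distractors so no bivariate
    order test can separate the classes.
    """
    from .io import LabeledDataset

    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    X = rng.normal(size=(n, p))
    y = np.array([1] * n_pos + [0] * n_neg)
    X[y == 1, feature] = threshold + rng.uniform(0.1, 1.0, size=n_pos)
    X[y == 0, feature] = threshold - rng.uniform(0.1, 1.0, size=n_neg)
    names = [f"M{j + 1}" for j in range(p)]
    return LabeledDataset(values=X, y=y, metabolite_names=names)


def make_rank_pair_dataset(
    n_pos: int = 20,
    n_neg: int = 20,
    p: int = 6,
    pair: tuple[int, int] = (0, 1),
    seed: int = 0,
):
    """Planted rank reversal: ``x[a] > x[b]`` in every positive, ``<`` in every
    negative, with strongly overlapping marginals so only the pair separates.
    """
    from .io import LabeledDataset

    rng = np.random.default_rng(seed)
    a, b = pair
    n = n_pos + n_neg
    X = rng.normal(size=(n, p))
    y = np.array([1] * n_pos + [0] * n_neg)
    base = rng.normal(0.0, 2.0, size=n)
    gap = rng.uniform(0.5, 1.5, size=n)
    X[:, b] = base
    X[:, a] = base + np.where(y == 1, gap, -gap)
    names = [f"M{j + 1}" for j in range(p)]
    return LabeledDataset(values=X, y=y, metabolite_names=names)
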