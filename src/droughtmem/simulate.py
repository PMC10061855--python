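"""Synthetic RNA-seq dataset generator with planted ground truth.

Emulates the recurring-drought expression design — two ecotypes (AEX, WW)
x three sampled treatments (R0 control, S1 first dehydration, S3 third
dehydration) x replicates — so that every downstream stage (normalization,
NB differential expression, trajectory classification, switch detection,
physiology) can be tested end-to-end without any sequencing data.

Counts are negative-binomial with Var = mu + dispersion * mu^2.  Each gene
carries one of the nine trajectory labels; its treatment means follow the
label's ordering with planted shifts of ``effect_log2fc`` log2 units, e.g.
a [+/-] gene has mean(S1) = mean(R0) * 2^effect_log2fc and mean(S3) back at
mean(R0).  Library sizes are equal by default (``size_factor_range``
widens them), isolating classification error from normalization error.

Switch modules are planted on top: each module has a latent log2 trajectory
(a memory pattern plus a shared per-sample jitter that makes the module
identifiable against same-category background genes); member genes and
positive TFs track the latent, negative TFs track its reflection about the
latent mean (keeping values positive and Pearson-valid), all with
independent N(0, noise_sd) jitter, so expected |r| exceeds 0.9 as
noise_sd -> 0.

Everything is driven by one integer seed; identical configs give
bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ALL_CATEGORIES, NONE_CATEGORY
from .errors import ConfigurationError
from .expression import CountMatrix, ECOTYPES, TREATMENTS
from .physiology import LeafWeightRecord, STAGES

# log2 multiplier applied at (R0, S1, S3), scaled by effect_log2fc
_CATEGORY_STEPS = {
    "[+/+]": (0.0, 1.0, 2.0),
    "[-/-]": (0.0, -1.0, -2.0),
    "[+/-]": (0.0, 1.0, 0.0),
    "[-/+]": (0.0, -1.0, 0.0),
    "[+/=]": (0.0, 1.0, 1.0),
    "[-/=]": (0.0, -1.0, -1.0),
    "[=/+]": (0.0, 0.0, 1.0),
    "[=/-]": (0.0, 0.0, -1.0),
    NONE_CATEGORY: (0.0, 0.0, 0.0),
}

DEFAULT_PROPORTIONS = {
    "[+/+]": 0.02,
    "[-/-]": 0.02,
    "[+/-]": 0.04,
    "[-/+]": 0.04,
    "[+/=]": 0.04,
    "[-/=]": 0.04,
    "[=/+]": 0.02,
    "[=/-]": 0.02,
    NONE_CATEGORY: 0.76,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic dataset.

    ``base_mean_log_range`` bounds the per-gene baseline mean expression in
    log2 units (default 2^4..2^10 counts).  ``dispersion`` is the NB alpha
    in Var = mu + alpha*mu^2.  ``module_jitter_sd`` is the SD (log2 units)
    of the shared per-sample wiggle on each module latent; ``noise_sd`` the
    per-gene jitter around it.  ``tfs_per_module`` is the (positive,
    negative) regulator count planted per module.
    """

    n_genes: int = 2000
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    base_mean_log_range: tuple[float, float] = (4.0, 10.0)
    effect_log2fc: float = 2.0
    dispersion: float = 0.05
    n_replicates: int = 2
    size_factor_range: tuple[float, float] = (1.0, 1.0)
    n_tfs: int = 20
    n_switch_modules: int = 2
    module_size_range: tuple[int, int] = (5, 10)
    tfs_per_module: tuple[int, int] = (1, 1)
    module_jitter_sd: float = 1.25
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        extra = set(self.category_proportions) - set(_CATEGORY_STEPS)
        if extra:
            raise ConfigurationError(f"unknown category labels: {sorted(extra)}")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"category_proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.category_proportions.values()):
            raise ConfigurationError("category proportions must be non-negative")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.effect_log2fc <= 0:
            raise ConfigurationError("effect_log2fc must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ConfigurationError("size_factor_range must be 0 < lo <= hi")
        lo, hi = self.module_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("module_size_range must be 0 < lo <= hi")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


@dataclass
class SimulatedDataset:
    """Synthetic counts plus the planted truth used to score recovery."""

    counts: CountMatrix
    gene_lengths: dict[str, float]
    truth_categories: dict[str, str]
    truth_regulators: list[str]
    truth_modules: list[tuple[frozenset[str], frozenset[str], frozenset[str]]]
    physiology: list[LeafWeightRecord] = field(default_factory=list)
    truth_profiles: pd.DataFrame | None = None  # continuous log2 module profiles

    def truth_dmgs(self, ecotype: str | None = None) -> set[str]:
        return {g for g, c in self.truth_categories.items() if c != NONE_CATEGORY}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.write(outdir / "counts.tsv", outdir / "design.tsv")
        pd.DataFrame(
            {"gene_id": list(self.gene_lengths), "length_bp": list(self.gene_lengths.values())}
        ).to_csv(outdir / "gene_lengths.tsv", sep="\t", index=False)
        truth = {
            "categories": self.truth_categories,
            "regulators": self.truth_regulators,
            "modules": [
                {"positive_tfs": sorted(p), "negative_tfs": sorted(n), "members": sorted(m)}
                for p, n, m in self.truth_modules
            ],
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
        with open(outdir / "regulators.txt", "w") as fh:
            fh.write("\n".join(self.truth_regulators) + ("\n" if self.truth_regulators else ""))
        if self.physiology:
            pd.DataFrame(
                [
                    {
                        "sample_id": r.sample_id, "ecotype": r.ecotype, "stage": r.stage,
                        "FW": r.fw, "TW": r.tw, "wilted": r.wilted, "DW": r.dw,
                    }
                    for r in self.physiology
                ]
            ).to_csv(outdir / "weights.tsv", sep="\t", index=False)


def _allocate_categories(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder allocation, then a seeded shuffle."""
    labels = [c for c in list(ALL_CATEGORIES) + [NONE_CATEGORY]
              if config.category_proportions.get(c, 0.0) > 0]
    fracs = np.array([config.category_proportions[c] for c in labels])
    raw = fracs * config.n_genes
    base = np.floor(raw).astype(int)
    remainder = config.n_genes - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:remainder]] += 1
    out = np.repeat(labels, base)
    return out[rng.permutation(config.n_genes)]


def generate_counts(config: SimulationConfig) -> SimulatedDataset:
    """NB counts for both ecotypes with planted trajectory categories."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"AS_{i:05d}" for i in range(config.n_genes)]
    categories = _allocate_categories(config, rng)

    base_log2 = rng.uniform(*config.base_mean_log_range, size=config.n_genes)
    steps = np.array([_CATEGORY_STEPS[c] for c in categories])  # genes x 3
    mean_log2 = base_log2[:, None] + steps * config.effect_log2fc  # at R0,S1,S3

    sample_ids, design_rows = [], []
    for eco in ECOTYPES:
        for tr in TREATMENTS:
            for rep in range(1, config.n_replicates + 1):
                sample_ids.append(f"{eco}_{tr}_{rep}")
                design_rows.append({"ecotype": eco, "treatment": tr, "replicate": rep})
    design = pd.DataFrame(design_rows, index=sample_ids)

    tr_index = {t: i for i, t in enumerate(TREATMENTS)}
    size_factors = rng.uniform(*config.size_factor_range, size=len(sample_ids))
    shape = 1.0 / config.dispersion  # NB "number of successes" parameter
    counts = np.empty((config.n_genes, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        mu = (2.0 ** mean_log2[:, tr_index[design.loc[sid, "treatment"]]]) * size_factors[j]
        p = shape / (shape + mu)
        counts[:, j] = rng.negative_binomial(shape, p)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids), design)
    lengths = dict(zip(genes, rng.integers(200, 5000, size=config.n_genes).astype(float)))

    # regulators are drawn among planted DMGs so the regulatory/functional
    # split keeps them in the regulatory half downstream
    dmg_idx = np.flatnonzero(categories != NONE_CATEGORY)
    pool = dmg_idx if len(dmg_idx) >= config.n_tfs else np.arange(config.n_genes)
    reg_idx = rng.choice(pool, size=min(config.n_tfs, len(pool)), replace=False)
    regulators = sorted(genes[i] for i in reg_idx)

    return SimulatedDataset(
        counts=cm,
        gene_lengths=lengths,
        truth_categories=dict(zip(genes, categories)),
        truth_regulators=regulators,
        truth_modules=[],
    )


def generate_switch_profiles(
    config: SimulationConfig, dataset: SimulatedDataset
) -> SimulatedDataset:
    """Overwrite selected gene rows with planted switch-module profiles.

    Module members and positive TFs follow a shared latent log2 trajectory
    (memory pattern [+/-] scaled by ``effect_log2fc``, plus a shared
    per-sample jitter); negative TFs follow the latent reflected about its
    per-ecotype mean (pattern [-/+]).  Truth categories of the planted
    genes are updated accordingly.
    """
    config.validate()
    if config.n_switch_modules == 0:
        return dataset
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_901]))
    genes = dataset.counts.gene_ids
    design = dataset.counts.design
    cats = dataset.truth_categories

    regulators = list(dataset.truth_regulators)
    n_pos, n_neg = config.tfs_per_module
    need_tfs = config.n_switch_modules * (n_pos + n_neg)
    if need_tfs > len(regulators):
        raise ConfigurationError(
            f"{need_tfs} module TFs requested but only {len(regulators)} regulators planted"
        )
    free_members = [
        g for g in genes if cats[g] != NONE_CATEGORY and g not in set(regulators)
    ]
    sizes = rng.integers(
        config.module_size_range[0], config.module_size_range[1] + 1,
        size=config.n_switch_modules,
    )
    if int(sizes.sum()) > len(free_members):
        raise ConfigurationError(
            f"module_size_range needs {int(sizes.sum())} member genes but only "
            f"{len(free_members)} non-regulator DMGs are available"
        )

    tf_pool = rng.permutation(regulators)
    member_pool = rng.permutation(free_members)
    counts = dataset.counts.values.copy()
    tr_index = {t: i for i, t in enumerate(TREATMENTS)}
    pattern = np.array(_CATEGORY_STEPS["[+/-]"]) * config.effect_log2fc

    profiles: dict[str, np.ndarray] = {}
    modules = []
    t_off = m_off = 0
    for _ in range(config.n_switch_modules):
        pos_tfs = list(tf_pool[t_off : t_off + n_pos]); t_off += n_pos
        neg_tfs = list(tf_pool[t_off : t_off + n_neg]); t_off += n_neg
        size = int(sizes[len(modules)])
        members = list(member_pool[m_off : m_off + size]); m_off += size

        latent = np.empty(len(design))
        reflected = np.empty_like(latent)
        for eco in ECOTYPES:
            cols = [i for i, s in enumerate(design.index) if design.loc[s, "ecotype"] == eco]
            treat = [tr_index[design.iloc[i]["treatment"]] for i in cols]
            z = pattern[treat] + rng.normal(0.0, config.module_jitter_sd, size=len(cols))
            latent[cols] = z
            reflected[cols] = 2.0 * z.mean() - z  # mirror about the ecotype mean

        # module genes are planted at mid-range baselines: high enough that
        # low-count rounding and the +1 offset of log2(FPKM+1) stay in the
        # transform's linear regime, low enough that their planted swings do
        # not visibly move per-sample library totals (the FPKM denominator)
        lo, hi = config.base_mean_log_range
        mid_lo = min(lo + 2.0, hi)
        mid_hi = min(mid_lo + 2.0, hi)
        base = rng.uniform(mid_lo, mid_hi, size=len(members) + n_pos + n_neg)
        planted = (
            [(g, latent, "[+/-]") for g in members]
            + [(g, latent, "[+/-]") for g in pos_tfs]
            + [(g, reflected, "[-/+]") for g in neg_tfs]
        )
        for (g, z, cat), b in zip(planted, base):
            log2prof = b + z + rng.normal(0.0, config.noise_sd, size=len(z))
            profiles[g] = log2prof
            counts.loc[g] = np.maximum(np.round(2.0 ** log2prof), 0).astype(np.int64)
            cats[g] = cat
        modules.append((frozenset(pos_tfs), frozenset(neg_tfs), frozenset(members)))

    new_counts = CountMatrix(counts, design.copy())
    prof_df = pd.DataFrame(profiles, index=design.index).T if profiles else None
    return replace(
        dataset,
        counts=new_counts,
        truth_categories=cats,
        truth_modules=modules,
        truth_profiles=prof_df,
    )


# stage -> (target RWC %, water-loss scale); drought stages sit lower
_STAGE_RWC = {
    "R0": 95.0, "S1": 70.0, "R1": 90.0, "S2": 74.0, "R2": 88.0, "S3": 78.0,
}
# the arid-land ecotype holds water better after the first stress
_WW_BONUS = {"R0": 0.0, "S1": 0.0, "R1": 2.0, "S2": 4.0, "R2": 3.0, "S3": 4.0}


def generate_physiology(
    config: SimulationConfig, n_per_group: int = 10
) -> list[LeafWeightRecord]:
    """Leaf weight records satisfying DW < wilted <= FW <= TW, with a
    planted drought effect (group mean RWC: R0 > S1)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11_213]))
    records = []
    for eco in ECOTYPES:
        for stage in STAGES:
            rwc_target = _STAGE_RWC[stage] + (_WW_BONUS[stage] if eco == "WW" else 0.0)
            for i in range(n_per_group):
                dw = rng.uniform(0.35, 0.6)
                capacity = rng.uniform(1.2, 1.8)  # TW - DW, g of water at saturation
                tw = dw + capacity
                rwc = np.clip(rng.normal(rwc_target, 3.0), 40.0, 100.0)
                fw = dw + capacity * rwc / 100.0
                wilted = dw + (fw - dw) * rng.uniform(0.25, 0.45)
                records.append(
                    LeafWeightRecord(
                        sample_id=f"{eco}_{stage}_{i+1}",
                        ecotype=eco, stage=stage,
                        fw=round(fw, 4), tw=round(tw, 4),
                        wilted=round(wilted, 4), dw=round(dw, 4),
                    ).validate()
                )
    return records


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Full generator: counts, switch profiles, physiology."""
    ds = generate_counts(config)
    ds = generate_switch_profiles(config, ds)
    ds.physiology = generate_physiology(config)
    return ds


def generate_orthogroups(
    dataset: SimulatedDataset,
    seed: int = 0,
    outgroup: str = "other_plants",
    p_shared: float = 0.25,
    p_focal: float = 0.25,
    p_a_only: float = 0.25,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Toy orthogroup table over the synthetic DMGs with known tier truth.

    The simulation uses one gene-ID space for both ecotypes, so an
    orthogroup spanning both focal columns simply lists the same gene ID in
    each.  Returns (Orthogroups.tsv-style frame, orthogroup -> true tier).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31_337]))
    dmgs = sorted(dataset.truth_dmgs())
    rows, truth = [], {}
    for i, g in enumerate(dmgs):
        og = f"OG{i:05d}"
        u = rng.random()
        if u < p_shared:
            tier, a, b, o = "shared", g, g, f"OUT|{g}"
        elif u < p_shared + p_focal:
            tier, a, b, o = "focal_shared", g, g, ""
        elif u < p_shared + p_focal + p_a_only:
            tier, a, b, o = "ecotype_a_unique", g, "", ""
        else:
            tier, a, b, o = "ecotype_b_unique", "", g, ""
        rows.append({"Orthogroup": og, "AEX": a, "WW": b, outgroup: o})
        truth[og] = tier
    return pd.DataFrame(rows), truth
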