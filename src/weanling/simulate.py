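"""Synthetic piglet cohort generator.

Emulates the cohort design every downstream stage expects: 5 litters x 4
piglets weaned into a challenging environment, a posteriori split into
diarrhoeic (D) and healthy (H) animals by fecal dry matter; 16S OTU counts
with negative-binomial noise and group effects planted in designated taxa;
electrophoresis fingerprint traces whose peak areas track OTU relative
abundances; qPCR runs following a log-linear standard curve; and dry-matter
series negatively coupled to Enterobacteriaceae load in D pigs only.

All randomness flows from one root seed through named independent
sub-streams (cohort, counts, traces, qpcr, phenotypes) so any stage can be
regenerated on its own, byte-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CohortPhenotypes, FingerprintProfile, GroundTruth, OTUTable, QpcrRun

__all__ = [
    "SimConfig",
    "generate_cohort",
    "simulate_otu_table",
    "simulate_fingerprints",
    "simulate_qpcr_run",
    "simulate_phenotypes",
    "simulate_pathway_matrix",
    "simulate_study",
    "PIG_GUT_FAMILIES",
]

# Common pig-gut 16S families used to label simulated OTUs.
PIG_GUT_FAMILIES = [
    ("Bacteroidetes", "Prevotellaceae", "Prevotella"),
    ("Firmicutes", "Lachnospiraceae", "Blautia"),
    ("Firmicutes", "Lachnospiraceae", "Roseburia"),
    ("Firmicutes", "Ruminococcaceae", "Faecalibacterium"),
    ("Firmicutes", "Ruminococcaceae", "Ruminococcus"),
    ("Firmicutes", "Lactobacillaceae", "Lactobacillus"),
    ("Fusobacteria", "Fusobacteriaceae", "Fusobacterium"),
    ("Actinobacteria", "Corynebacteriaceae", "Corynebacterium"),
    ("Firmicutes", "Clostridiaceae", "Clostridium"),
    ("Firmicutes", "Enterococcaceae", "Enterococcus"),
    ("Proteobacteria", "Enterobacteriaceae", "Escherichia"),
    ("Firmicutes", "Veillonellaceae", "Succiniclasticum"),
    ("Actinobacteria", "Actinomycetaceae", "Actinomyces"),
    ("Bacteroidetes", "Bacteroidaceae", "Bacteroides"),
]

QPCR_TARGETS = ["total", "Firmicutes", "Bacteroidetes", "Lactobacillus", "Enterobacteriaceae"]
QPCR_DAYS = [14, 21, 30, 38, 47]

_STREAMS = ("cohort", "counts", "traces", "qpcr", "phenotypes", "pathways")


@dataclass
class SimConfig:
    """Parameters of the stated in-silico world.

    Defaults reproduce the study design: 5 litters x 4 piglets (2 male,
    2 female each), per-litter diarrhoea prevalence emulating the 13 D / 7 H
    outcome, a diarrhoea onset window at post-natal days 38-42, and
    moderately overdispersed counts (variance = mu + phi * mu^2).
    """

    n_litters: int = 5
    pigs_per_litter: int = 4
    d_per_litter: tuple[int, ...] = (3, 3, 3, 2, 2)
    n_otus: int = 150
    n_discriminant: int = 15
    logfc_effects: dict[str, float] | None = None
    effect_size: float = 3.0          # |log2 FC| planted when logfc_effects is None
    dispersion: float = 0.2           # NB phi, var = mu + phi mu^2
    library_size_range: tuple[int, int] = (8000, 12000)
    seed: int = 0
    entero_dm_slope: float = -3.0     # DM% change per log10 Enterobacteriaceae excess, D pigs
    qpcr_efficiency: float = 0.95
    qpcr_intercept: float = 38.0      # Cq at a single template copy
    qpcr_noise_sd: float = 0.0
    trace_noise_sd: float = 0.0
    trace_shift_max: float = 0.0      # per-sample scan-unit shift, uniform(-max, +max)
    peak_sigma: float = 1.2           # Gaussian peak width, size units
    standard_sizes: tuple[float, ...] = (50.0, 150.0, 250.0, 350.0, 450.0)
    position_range: tuple[float, float] = (80.0, 480.0)
    co_migration: bool = False        # force shared peak positions (stress test)
    onset_window: tuple[int, int] = (38, 42)
    dm_days: tuple[int, ...] = tuple(range(30, 48))
    dm_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.n_litters <= 0 or self.pigs_per_litter <= 0:
            raise ValueError("litter counts must be positive")
        if len(self.d_per_litter) != self.n_litters:
            raise ValueError("d_per_litter must have one entry per litter")
        if any(d < 0 or d > self.pigs_per_litter for d in self.d_per_litter):
            raise ValueError("per-litter D counts must lie in [0, pigs_per_litter]")
        if self.n_discriminant > self.n_otus:
            raise ValueError("n_discriminant cannot exceed n_otus")
        if self.dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        if min(self.library_size_range) <= 0:
            raise ValueError("library sizes must be positive")
        if not (0.7 < self.qpcr_efficiency <= 1.1):
            raise ValueError("qPCR efficiency must lie in (0.7, 1.1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child generator; independent across stream names."""
        idx = _STREAMS.index(stream)
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,)))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _otu_ids(config: SimConfig) -> list[str]:
    return [f"OTU{i:04d}" for i in range(1, config.n_otus + 1)]


def _taxonomy(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Assign each OTU a lineage from the bundled pig-gut taxon list.

    The first OTUs cycle through the list deterministically so every family
    (including Enterobacteriaceae, needed for phenotype coupling) is present.
    """
    ids = _otu_ids(config)
    rows = []
    for i in range(config.n_otus):
        phylum, family, genus = PIG_GUT_FAMILIES[i % len(PIG_GUT_FAMILIES)]
        rows.append(f"k__Bacteria;p__{phylum};f__{family};g__{genus}")
    return pd.Series(rows, index=ids, name="taxonomy")


def default_effects(config: SimConfig) -> dict[str, float]:
    """Planted log2 fold changes (H vs D), alternating sign, on the first
    ``n_discriminant`` OTUs."""
    if config.logfc_effects is not None:
        return dict(config.logfc_effects)
    ids = _otu_ids(config)
    return {
        ids[i]: config.effect_size * (1 if i % 2 == 0 else -1)
        for i in range(config.n_discriminant)
    }


def generate_cohort(config: SimConfig) -> tuple[CohortPhenotypes, GroundTruth]:
    """Build the cohort skeleton: litters, sexes, H/D labels.

    Within each litter, which pigs are labelled D is drawn at random; sexes
    are balanced (half male, half female, extra pig male on odd sizes).
    """
    rng = config.rng("cohort")
    rows = []
    labels: dict[str, str] = {}
    for lit in range(1, config.n_litters + 1):
        n = config.pigs_per_litter
        d_idx = rng.choice(n, size=config.d_per_litter[lit - 1], replace=False)
        sexes = ["M"] * (n - n // 2) + ["F"] * (n // 2)
        rng.shuffle(sexes)
        for j in range(n):
            pig = f"L{lit}P{j + 1}"
            group = "D" if j in d_idx else "H"
            labels[pig] = group
            rows.append({"pig": pig, "litter": lit, "sex": sexes[j], "group": group})
    pigs = pd.DataFrame(rows).set_index("pig", drop=False)
    effects = default_effects(config)
    truth = GroundTruth(group_labels=labels, true_effects=effects)
    return CohortPhenotypes(pigs=pigs), truth


def simulate_otu_table(
    cohort: CohortPhenotypes,
    truth: GroundTruth,
    config: SimConfig,
    day: int = 7,
) -> OTUTable:
    """Draw the OTU count matrix (one sample per pig at ``day``).

    Per-cell counts are NB with mean = baseline_i * libsize_j *
    2^(+effect/2) in H and 2^(-effect/2) in D (symmetric multiplicative
    effect: swapping labels negates the log fold change exactly) and
    variance = mu + phi mu^2. phi = 0 degenerates to Poisson.
    """
    rng = config.rng("counts")
    ids = _otu_ids(config)
    taxonomy = _taxonomy(config, rng)
    # log-normal baseline relative abundances, heavy-tailed like real 16S data
    base = np.exp(rng.normal(0.0, 1.2, size=config.n_otus))
    base /= base.sum()
    pigs = list(cohort.pigs["pig"])
    lo, hi = config.library_size_range
    libs = rng.integers(lo, hi + 1, size=len(pigs))
    eff = np.array([truth.true_effects.get(o, 0.0) for o in ids])
    counts = np.empty((config.n_otus, len(pigs)), dtype=np.int64)
    for j, pig in enumerate(pigs):
        sign = +0.5 if truth.group_labels[pig] == "H" else -0.5
        mu = base * libs[j] * np.power(2.0, sign * eff)
        if config.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / config.dispersion
            p = r / (r + mu)
            counts[:, j] = rng.negative_binomial(r, p)
    samples = [f"{pig}_d{day}" for pig in pigs]
    meta = pd.DataFrame(
        {
            "pig": pigs,
            "group": [truth.group_labels[p] for p in pigs],
            "day": day,
            "litter": list(cohort.pigs["litter"]),
        },
        index=samples,
    )
    return OTUTable(
        counts=pd.DataFrame(counts, index=ids, columns=samples),
        taxonomy=taxonomy,
        sample_meta=meta,
    )


def phylotype_positions(config: SimConfig) -> pd.Series:
    """Injective OTU -> electrophoretic position map (size units).

    Evenly spaced across the informative window with a small deterministic
    jitter; with ``co_migration`` every third OTU collapses onto its
    predecessor's position (stress test for peak binning).
    """
    rng = config.rng("traces")
    lo, hi = config.position_range
    pos = np.linspace(lo, hi, config.n_otus)
    if config.n_otus > 1:
        gap = (hi - lo) / (config.n_otus - 1)
        pos = pos + rng.uniform(-0.2, 0.2, size=config.n_otus) * gap
        pos = np.sort(pos)
    if config.co_migration:
        for i in range(2, config.n_otus, 3):
            pos[i] = pos[i - 1]
    return pd.Series(pos, index=_otu_ids(config))


def simulate_fingerprints(
    table: OTUTable, config: SimConfig
) -> dict[str, FingerprintProfile]:
    """Render each sample's trace as a sum of Gaussian peaks.

    Peak area is proportional to the OTU's relative abundance; a smooth
    baseline, white noise, and a per-sample scan shift are added; internal
    size-standard peaks are reported at their observed (shifted) positions.
    """
    if table.n_samples == 0:
        raise ValueError("empty OTU table")
    # sub-stream disjoint from the one phylotype_positions consumes
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS.index("traces"), 1))
    )
    positions = phylotype_positions(config).values
    grid = np.arange(0.0, 520.0 + 1e-9, 0.25)
    sigma = config.peak_sigma
    rel = table.counts / table.counts.sum(axis=0)
    profiles: dict[str, FingerprintProfile] = {}
    for sample in table.counts.columns:
        shift = rng.uniform(-config.trace_shift_max, config.trace_shift_max)
        ab = rel[sample].values
        trace = np.zeros_like(grid)
        for p, a in zip(positions, ab):
            if a <= 0:
                continue
            trace += a * np.exp(-0.5 * ((grid - (p + shift)) / sigma) ** 2)
        # smooth baseline: gentle arch over the whole trace
        baseline = 0.02 * np.max(trace, initial=0.0) * np.sin(np.pi * grid / grid[-1])
        trace = trace + baseline
        if config.trace_noise_sd > 0:
            trace = trace + rng.normal(0.0, config.trace_noise_sd, size=grid.size)
        trace = np.clip(trace, 0.0, None)
        std_peaks = [(s + shift, s) for s in config.standard_sizes]
        profiles[sample] = FingerprintProfile(
            sample_id=sample, positions=grid.copy(), intensities=trace,
            standard_peaks=std_peaks,
        )
    return profiles


def _true_copy_table(truth: GroundTruth, cohort: CohortPhenotypes, config: SimConfig) -> pd.DataFrame:
    """Ground-truth copies per 100 ug DNA per (pig, day, target).

    Enterobacteriaceae load spikes in D pigs during their diarrhoea episode;
    other targets fluctuate around group-independent baselines.
    """
    rng = config.rng("qpcr")
    base_log10 = {
        "total": 9.0,
        "Firmicutes": 8.5,
        "Bacteroidetes": 8.0,
        "Lactobacillus": 7.0,
        "Enterobacteriaceae": 6.0,
    }
    rows = []
    for pig in cohort.pigs["pig"]:
        group = truth.group_labels[pig]
        # per-pig Enterobacteriaceae excess; elevated from PND 30 in D pigs,
        # anticipating the diarrhoea episode
        excess = rng.uniform(0.5, 2.5)
        for day in QPCR_DAYS:
            for target in QPCR_TARGETS:
                logc = base_log10[target] + rng.normal(0.0, 0.25)
                if target == "Enterobacteriaceae" and group == "D" and day >= 30:
                    logc += excess * (1.0 if day >= 38 else 0.5)
                rows.append({"pig": pig, "day": day, "target": target,
                             "copies_per_100ug": 10.0 ** logc})
    return pd.DataFrame(rows)


def _episode_onsets(truth: GroundTruth, config: SimConfig) -> dict[str, int]:
    """First sub-20% DM day per D pig, uniform on the onset window."""
    rng = config.rng("phenotypes")
    lo, hi = config.onset_window
    onsets = {}
    for pig in sorted(truth.group_labels):
        onsets[pig] = int(rng.integers(lo, hi + 1))  # drawn for H too, unused
    return onsets


def simulate_qpcr_run(
    truth: GroundTruth,
    config: SimConfig,
    target: str = "Enterobacteriaceae",
    day: int = 38,
) -> QpcrRun:
    """Standards on a 10-fold dilution series plus per-pig unknowns.

    Cq = intercept - log10(copies) / log10(1 + efficiency) + noise; sample
    Cq is generated from the pig's true copies scaled by its DNA input mass.
    """
    if truth.true_copies.empty:
        raise ValueError("ground truth has no copy numbers; run simulate_phenotypes first")
    # per-(target, day) sub-stream, disjoint from the copy-table draws
    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.seed,
            spawn_key=(_STREAMS.index("qpcr"), 1, QPCR_TARGETS.index(target), day),
        )
    )
    slope = -1.0 / np.log10(1.0 + config.qpcr_efficiency)
    std_copies = 10.0 ** np.arange(3, 11)
    std_cq = config.qpcr_intercept + slope * np.log10(std_copies)
    if config.qpcr_noise_sd > 0:
        std_cq = std_cq + rng.normal(0.0, config.qpcr_noise_sd, size=std_cq.size)
    standards = pd.DataFrame({"copies": std_copies, "cq": std_cq})
    sub = truth.true_copies.query("target == @target and day == @day")
    rows = []
    for _, rec in sub.iterrows():
        if rec["copies_per_100ug"] <= 0:
            raise ValueError("copy numbers must be positive")
        mass = rng.uniform(60.0, 140.0)
        reaction_copies = rec["copies_per_100ug"] * mass / 100.0
        cq = config.qpcr_intercept + slope * np.log10(reaction_copies)
        if config.qpcr_noise_sd > 0:
            cq += rng.normal(0.0, config.qpcr_noise_sd)
        rows.append({"sample": f"{rec['pig']}_d{day}", "target": target,
                     "cq": cq, "dna_mass_ug": mass})
    return QpcrRun(standards=standards, samples=pd.DataFrame(rows), target=target)


def simulate_phenotypes(
    cohort: CohortPhenotypes, truth: GroundTruth, config: SimConfig
) -> tuple[CohortPhenotypes, GroundTruth]:
    """Fill in dry-matter series, MUC13 amplicons and colostrum records.

    D pigs get a 2-3 day diarrhoea episode whose sub-20% DM depth follows
    the pig's simulated Enterobacteriaceae excess with slope
    ``entero_dm_slope`` (DM%% per log10 copies); H pigs stay above 20%% DM
    throughout. MUC13 alleles are drawn independently of group.
    """
    truth.true_copies = _true_copy_table(truth, cohort, config)
    # sub-stream disjoint from the onset draws of _episode_onsets
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS.index("phenotypes"), 1))
    )
    onsets = _episode_onsets(truth, config)
    entero = truth.true_copies.query("target == 'Enterobacteriaceae'")
    entero_by = {(r["pig"], r["day"]): r["copies_per_100ug"] for _, r in entero.iterrows()}
    base_entero_log10 = 6.0
    dm_rows = []
    pig_rows = []
    for pig in cohort.pigs["pig"]:
        group = truth.group_labels[pig]
        onset = onsets[pig]
        duration = int(rng.integers(2, 4))  # 2-3 consecutive days
        for day in config.dm_days:
            healthy_dm = rng.uniform(24.0, 34.0)
            in_episode = group == "D" and onset <= day < onset + duration
            if in_episode:
                # the PND 38 Enterobacteriaceae load drives episode severity
                excess = np.log10(entero_by[(pig, 38)]) - base_entero_log10
                dm = 19.5 + config.entero_dm_slope * max(excess, 0.0)
                dm += rng.normal(0.0, config.dm_noise_sd * 0.1)
                dm = float(np.clip(dm, 2.0, 19.9))
            else:
                dm = float(np.clip(healthy_dm + rng.normal(0.0, config.dm_noise_sd), 20.5, 45.0))
            dm_rows.append({"pig": pig, "day": day, "dm_pct": dm})
        alleles = rng.choice([151.0, 83.0], size=2, p=[0.6, 0.4])
        intake = float(np.clip(rng.normal(300.0, 50.0), 100.0, 500.0))
        pig_rows.append({
            "pig": pig,
            "muc13_len1": float(alleles[0]),
            "muc13_len2": float(alleles[1]),
            "colostrum_intake_ml": intake,
            "igg_mg_per_ml": float(np.clip(rng.normal(60.0, 10.0), 20.0, 120.0)),
            "iga_mg_per_ml": float(np.clip(rng.normal(10.0, 2.0), 2.0, 25.0)),
            "tgfb1_ng_per_ml": float(np.clip(rng.normal(250.0, 60.0), 50.0, 600.0)),
        })
    extra = pd.DataFrame(pig_rows).set_index("pig")
    pigs = cohort.pigs.join(extra)
    return CohortPhenotypes(pigs=pigs, dm=pd.DataFrame(dm_rows)), truth


def simulate_pathway_matrix(
    table: OTUTable, config: SimConfig, n_pathways: int = 40
) -> pd.DataFrame:
    """Stand-in for imputed pathway abundances (samples x pathways).

    Each pathway is a sparse nonnegative mixture of OTU relative abundances
    plus noise — enough structure for association-matrix tests, with no
    claim to emulate real functional imputation.
    """
    rng = config.rng("pathways")
    rel = (table.counts / table.counts.sum(axis=0)).T  # samples x OTUs
    w = rng.uniform(0.0, 1.0, size=(table.n_otus, n_pathways))
    w *= rng.random(size=w.shape) < 0.1  # ~10% of OTUs load on each pathway
    path = rel.values @ w
    path += rng.normal(0.0, 0.05 * max(path.std(), 1e-12), size=path.shape)
    cols = [f"ko{i:05d}" for i in range(1, n_pathways + 1)]
    return pd.DataFrame(np.clip(path, 0.0, None), index=rel.index, columns=cols)


def simulate_study(config: SimConfig) -> dict:
    """Run every generator stage; returns a bundle keyed by stage name."""
    cohort, truth = generate_cohort(config)
    cohort, truth = simulate_phenotypes(cohort, truth, config)
    table = simulate_otu_table(cohort, truth, config)
    fingerprints = simulate_fingerprints(table, config)
    qpcr = {
        (t, d): simulate_qpcr_run(truth, config, target=t, day=d)
        for t in QPCR_TARGETS
        for d in (30, 38)
    }
    pathways = simulate_pathway_matrix(table, config)
    return {
        "config": config,
        "cohort": cohort,
        "truth": truth,
        "otu_table": table,
        "fingerprints": fingerprints,
        "qpcr": qpcr,
        "pathways": pathways,
    }
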