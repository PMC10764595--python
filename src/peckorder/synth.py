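"""Synthetic study generator: hens, competition scores, feeder logs, microbiome.

Emulates a 4-pen x 10-hen layer-hen study. Each hen carries a latent dominance
score theta; feeding-competition scores arise from a noisy theta ordering
against a limited-capacity feeder; precision-feeder event logs, body weights,
organ weights, vigilance scores and a cecal ASV count table are generated with
the group structure the downstream analysis assumes (HR hens visit the feeder
more and eat more per day; LR hens eat more per visit; HR ceca are less rich,
with taxon-specific abundance shifts).

Randomness is splittable: every generator derives its own named stream from
``cfg.seed`` (stream order: profiles, competition, feeder, weights, organs,
vigilance, asv), so regenerating one output never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .microbiome import AsvTable

__all__ = [
    "SynthConfig",
    "MOCK_LINEAGES",
    "make_profiles",
    "attainable_ranks",
    "rank_recovery",
    "generate_competition",
    "generate_feeder_events",
    "generate_body_weights",
    "generate_organs",
    "generate_vigilance",
    "generate_asv_table",
    "base_alpha",
    "generate_all",
    "write_dataset",
]

_STREAMS = ["profiles", "competition", "feeder", "weights", "organs",
            "vigilance", "asv"]

# Mock 7-rank lineages covering the cecal phyla/genera the analysis reports.
# (phylum, class, order, family, genus, weight); genus "unclassified" entries
# exercise the "<parent> unclassified" labelling downstream.
MOCK_LINEAGES: list[tuple[str, str, str, str, str, float]] = [
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", 0.16),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Rikenellaceae RC9 gut group", 0.12),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes", 0.06),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Barnesiellaceae", "unclassified", 0.05),
    ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", "Eubacterium hallii group", 0.06),
    ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", "Anaerostipes", 0.05),
    ("Firmicutes", "Clostridia", "Oscillospirales", "Oscillospiraceae", "Subdoligranulum", 0.06),
    ("Firmicutes", "Clostridia", "Oscillospirales", "Oscillospiraceae", "Faecalibacterium", 0.07),
    ("Firmicutes", "Clostridia", "Clostridia UCG-014", "Clostridia UCG-014", "unclassified", 0.10),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", 0.05),
    ("Proteobacteria", "Gammaproteobacteria", "Aeromonadales", "Succinivibrionaceae", "Succinatimonas", 0.06),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia-Shigella", 0.06,),
    ("Deferribacterota", "Deferribacteres", "Deferribacterales", "Deferribacteraceae", "Mucispirillum", 0.05),
    ("Actinobacteriota", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", 0.05),
]

# Positive log-fold = more abundant in HR; mirrors the directional findings
# the downstream differential-abundance stage is meant to recover.
DEFAULT_EFFECT_TAXA: dict[str, float] = {
    "Firmicutes": 0.8,
    "Deferribacterota": -0.8,
    "Succinatimonas": 1.0,
    "Eubacterium hallii group": 1.0,
    "Anaerostipes": 1.0,
    "Bacteroides": -0.8,
    "Mucispirillum": -1.0,
    "Subdoligranulum": -1.0,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study-design constants and generator knobs.

    Defaults mirror the emulated design: 4 pens of 10 hens, 6 ten-minute
    feeding-competition tests scored at 30-s intervals (20 intervals per
    test), a feeder admitting 2-4 birds at once, feeder monitoring over days
    67-90 of age, and n=8 cecal samples per rank group.
    """

    n_pens: int = 4
    n_hens_per_pen: int = 10
    n_tests: int = 6
    n_intervals: int = 20
    feeder_capacity: int = 3      # hens scoring 3 (feeding) simultaneously
    score2_band: int = 2          # hens scoring 2 (close, motivated)
    score1_band: int = 2          # hens scoring 1 (displaced, circling)
    noise_sd: float = 1.0         # SD of per-interval perception noise on theta
    seed: int = 0
    # feeder-log generation
    days: int = 24                # days of age 67..90 inclusive
    first_day: int = 67
    visits_mean: dict = field(default_factory=lambda: {"HR": 30.0, "LR": 20.0, "MID": 25.0})
    intake_per_visit_mean: dict = field(default_factory=lambda: {"HR": 6.0, "LR": 8.0, "MID": 7.0})
    intake_shape: float = 8.0     # Gamma shape for per-visit intake
    occupation_s_per_g: float = 12.0
    # microbiome generation
    dm_concentration: float = 50.0
    n_taxa: int = 300
    depth_mean: int = 20000
    effect_taxa: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_TAXA))
    hr_zero_fraction: float = 0.15  # rarest ASVs structurally absent in HR

    def __post_init__(self) -> None:
        if not (2 <= self.feeder_capacity <= 4):
            raise ValueError("feeder_capacity must be between 2 and 4")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.dm_concentration <= 0:
            raise ValueError("dm_concentration must be positive")
        if not (0 <= self.hr_zero_fraction < 1):
            raise ValueError("hr_zero_fraction must be in [0, 1)")

    def stream(self, name: str) -> np.random.Generator:
        """Named child RNG; independent of draws on any other stream."""
        i = _STREAMS.index(name)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(i,)))

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


def make_profiles(cfg: SynthConfig) -> pd.DataFrame:
    """Latent dominance profiles: one row per hen with pen and theta ~ N(0,1)."""
    rng = cfg.stream("profiles")
    rows = []
    hen_no = 0
    for p in range(1, cfg.n_pens + 1):
        for _ in range(cfg.n_hens_per_pen):
            hen_no += 1
            rows.append({"hen": f"hen{hen_no:02d}", "pen": f"pen{p}",
                         "theta": rng.normal(0.0, 1.0)})
    return pd.DataFrame(rows).set_index("hen")


def generate_competition(profiles: pd.DataFrame, cfg: SynthConfig) -> pd.DataFrame:
    """Interval-wise 0-3 competition scores from noisy theta orderings.

    At every interval of every test, hens in a pen are ordered by
    theta + N(0, noise_sd); the top ``feeder_capacity`` hens score 3 (feeding),
    the next ``score2_band`` score 2, the next ``score1_band`` score 1, the
    rest score 0.
    """
    if profiles.index.duplicated().any():
        raise ValueError("duplicate hen ids in profiles")
    if not np.isfinite(profiles["theta"]).all():
        raise ValueError("theta must be finite")
    rng = cfg.stream("competition")
    bands = [(3, cfg.feeder_capacity), (2, cfg.score2_band), (1, cfg.score1_band)]
    records = []
    for pen, pen_prof in profiles.groupby("pen", sort=True):
        theta = pen_prof["theta"].to_numpy(float)
        hens = pen_prof.index.to_numpy()
        n = len(hens)
        for test in range(1, cfg.n_tests + 1):
            for interval in range(1, cfg.n_intervals + 1):
                perceived = theta + rng.normal(0.0, cfg.noise_sd, size=n)
                # stable descending order; hen id breaks exact float ties
                order = np.lexsort((hens, -perceived))
                scores = np.zeros(n, dtype=int)
                pos = 0
                for score, width in bands:
                    scores[order[pos:pos + width]] = score
                    pos += width
                for h, s in zip(hens, scores):
                    records.append((pen, h, test, interval, s))
    return pd.DataFrame(records, columns=["pen", "hen", "test", "interval", "score"])


def attainable_ranks(profiles: pd.DataFrame, cfg: SynthConfig) -> pd.Series:
    """The finest ranking the band scoring can reveal at zero noise.

    With a deterministic emission rule, hens inside one score band receive
    identical sums at every interval, so they are informationally
    indistinguishable: the best any rank aggregation can do is order the
    bands and tie within them. Returns, per hen, the average rank of its
    theta-band (1 = most dominant).
    """
    out = {}
    for _, pen_prof in profiles.groupby("pen", sort=True):
        order = pen_prof["theta"].sort_values(ascending=False).index
        n = len(order)
        widths = [cfg.feeder_capacity, cfg.score2_band, cfg.score1_band]
        widths.append(max(n - sum(widths), 0))
        pos = 0
        for w in widths:
            band = order[pos:pos + w]
            avg = (2 * pos + len(band) + 1) / 2.0  # mean of ranks pos+1..pos+len
            for h in band:
                out[h] = avg
            pos += len(band)
    return pd.Series(out, name="attainable_rank").reindex(profiles.index)


def rank_recovery(profiles: pd.DataFrame, rank_table: pd.DataFrame,
                  cfg: SynthConfig) -> float:
    """Mean per-pen Spearman rho between recovered and attainable ranks."""
    from scipy.stats import spearmanr

    target = attainable_ranks(profiles, cfg)
    rhos = []
    for _, sub in rank_table.groupby("pen"):
        rhos.append(spearmanr(sub["final_rank"],
                              target.loc[sub.index]).statistic)
    return float(np.mean(rhos))


def generate_feeder_events(rank_table: pd.DataFrame, cfg: SynthConfig,
                           days: int | None = None) -> pd.DataFrame:
    """Precision-feeder visit log with HR/LR contrasts built in.

    Per hen per day: visit count ~ Poisson(group mean); per-visit intake ~
    Gamma with a higher mean for LR than HR (LR hens eat more per sitting);
    occupation time proportional to intake with lognormal noise. Visits are
    laid out sequentially from 08:00 so one hen's events never overlap.
    """
    days = cfg.days if days is None else days
    if days < 1:
        raise ValueError("days must be >= 1")
    if "group" not in rank_table.columns:
        raise ValueError("rank table must carry HR/LR/MID group labels")
    rng = cfg.stream("feeder")
    records = []
    for hen, row in rank_table.iterrows():
        g = row["group"]
        lam = cfg.visits_mean[g]
        mean_intake = cfg.intake_per_visit_mean[g]
        scale = mean_intake / cfg.intake_shape
        for d in range(days):
            day = cfg.first_day + d
            n_visits = rng.poisson(lam)
            t = 8 * 3600.0
            for _ in range(n_visits):
                t += rng.exponential(120.0)  # wait before next visit
                intake = max(rng.gamma(cfg.intake_shape, scale), 1e-3)
                duration = intake * cfg.occupation_s_per_g * rng.lognormal(0.0, 0.1)
                records.append((hen, day, round(t, 1), round(duration, 1),
                                round(intake, 3)))
                t += duration
    return pd.DataFrame(records,
                        columns=["hen", "date", "start", "duration_s", "intake_g"])


def generate_body_weights(rank_table: pd.DataFrame, cfg: SynthConfig) -> pd.DataFrame:
    """Daily body weights: start ~N(1000, 50) g, gain ~N(20, 3) g/d.

    Growth is drawn identically for every group — the emulated study found no
    rank difference in body weight or daily gain.
    """
    rng = cfg.stream("weights")
    records = []
    for hen in rank_table.index:
        bw = rng.normal(1000.0, 50.0)
        adg = rng.normal(20.0, 3.0)
        for d in range(cfg.days):
            w = bw + adg * d + rng.normal(0.0, 5.0)
            records.append((hen, cfg.first_day + d, round(w, 1)))
    return pd.DataFrame(records, columns=["hen", "date", "weight_g"])


# organ-index (g/kg) group means/SDs used by the organ generator
_ORGAN_INDEX = {
    "bursa": {"HR": (1.25, 0.56), "LR": (1.26, 0.73), "MID": (1.25, 0.6)},
    "heart": {"HR": (4.82, 0.71), "LR": (4.03, 0.29), "MID": (4.4, 0.5)},
    "liver": {"HR": (16.71, 1.15), "LR": (18.40, 8.32), "MID": (17.5, 4.0)},
    "spleen": {"HR": (1.73, 0.22), "LR": (2.38, 2.01), "MID": (2.0, 1.0)},
}


def generate_organs(rank_table: pd.DataFrame, cfg: SynthConfig,
                    final_weights: pd.Series | None = None) -> pd.DataFrame:
    """Slaughter-day organ weights consistent with g/kg organ-index contrasts."""
    rng = cfg.stream("organs")
    records = []
    for hen, row in rank_table.iterrows():
        g = row["group"]
        bw = float(final_weights[hen]) if final_weights is not None else rng.normal(1450.0, 80.0)
        for organ, params in _ORGAN_INDEX.items():
            m, s = params[g]
            idx = max(rng.normal(m, s), 0.05)  # index g/kg, kept positive
            records.append((hen, organ, round(idx * bw / 1000.0, 3), round(bw, 1)))
    return pd.DataFrame(records, columns=["hen", "organ", "organ_weight_g",
                                          "body_weight_g"])


def generate_vigilance(groups: pd.Series,
                       probs_hr=(0.0, 0.0, 1.0),
                       probs_lr=(0.125, 0.5, 0.375),
                       cfg: SynthConfig | None = None,
                       n_sessions: int = 1) -> pd.DataFrame:
    """Ordinal 0-2 vigilance scores, one categorical draw per hen per session.

    Defaults reproduce in expectation the observed proportions of the
    emulated study (all HR hens maximally vigilant; LR split 12.5/50/37.5%).
    """
    cfg = cfg or SynthConfig()
    for name, p in (("probs_hr", probs_hr), ("probs_lr", probs_lr)):
        p = np.asarray(p, float)
        if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError(f"{name} must be 3 nonnegative probabilities summing to 1")
    rng = cfg.stream("vigilance")
    probs = {"HR": np.asarray(probs_hr, float), "LR": np.asarray(probs_lr, float),
             "MID": np.array([0.1, 0.5, 0.4])}
    records = []
    for hen, g in groups.items():
        for s in range(1, n_sessions + 1):
            score = int(rng.choice(3, p=probs[g]))
            records.append((hen, f"s{s}", score))
    return pd.DataFrame(records, columns=["hen", "session", "score"])


def _lineage_string(entry) -> str:
    p, c, o, f, g, _ = entry
    return (f"k__Bacteria; p__{p}; c__{c}; o__{o}; f__{f}; "
            f"g__{g}; s__unclassified")


def _assign_taxonomy(cfg: SynthConfig, rng: np.random.Generator):
    """Map each ASV to a mock lineage; every genus gets at least one ASV."""
    weights = np.array([e[-1] for e in MOCK_LINEAGES])
    weights = weights / weights.sum()
    n_lin = len(MOCK_LINEAGES)
    if cfg.n_taxa < n_lin:
        raise ValueError(f"n_taxa must be >= {n_lin} to cover the mock lineage table")
    idx = np.concatenate([np.arange(n_lin),
                          rng.choice(n_lin, size=cfg.n_taxa - n_lin, p=weights)])
    return idx


def base_alpha(cfg: SynthConfig) -> np.ndarray:
    """Deterministic base composition (sums to 1) shared by both groups.

    Heavy-tailed lognormal relative abundances, so the table has a realistic
    mix of dominant and rare ASVs. Drawn on the 'asv' stream before any
    count sampling, hence stable across partial reruns.
    """
    rng = cfg.stream("asv")
    props = rng.lognormal(0.0, 1.5, size=cfg.n_taxa)
    return props / props.sum()


def generate_asv_table(groups: pd.Series, cfg: SynthConfig) -> AsvTable:
    """Dirichlet-multinomial ASV counts with group effects and HR rare-taxon loss.

    Each sample's composition is Dirichlet(dm_concentration * base), where the
    base proportions of effect taxa are multiplied by exp(log-fold) for HR
    samples; counts are Multinomial at depth ~ Poisson(depth_mean). The
    ``hr_zero_fraction`` rarest ASVs are structurally zeroed in HR samples, so
    expected observed richness is lower in HR without an evenness shift.
    """
    rng = cfg.stream("asv")
    props = rng.lognormal(0.0, 1.5, size=cfg.n_taxa)  # same draw as base_alpha
    base = props / props.sum()
    lin_idx = _assign_taxonomy(cfg, rng)

    known = set()
    for p, c, o, f, g, _ in MOCK_LINEAGES:
        known.add(p)
        known.add(g if g != "unclassified" else f"{f} unclassified")
    for taxon in cfg.effect_taxa:
        if taxon not in known:
            raise ValueError(f"effect taxon {taxon!r} not in the mock taxonomy table")

    asv_ids = [f"ASV{i + 1:04d}" for i in range(cfg.n_taxa)]
    phylum = np.array([MOCK_LINEAGES[i][0] for i in lin_idx])
    genus = np.array([
        MOCK_LINEAGES[i][4] if MOCK_LINEAGES[i][4] != "unclassified"
        else f"{MOCK_LINEAGES[i][3]} unclassified"
        for i in lin_idx])

    log_effect = np.zeros(cfg.n_taxa)
    for taxon, eff in cfg.effect_taxa.items():
        log_effect[(phylum == taxon) | (genus == taxon)] += eff

    n_zero = int(round(cfg.hr_zero_fraction * cfg.n_taxa))
    rare_set = np.argsort(base)[:n_zero]  # structurally absent in HR ceca

    counts = {}
    for hen in groups.index:
        alpha = base.copy()
        if groups[hen] == "HR":
            alpha = alpha * np.exp(log_effect)
            alpha[rare_set] = 0.0
        alive = alpha > 0
        comp = np.zeros(cfg.n_taxa)
        comp[alive] = rng.dirichlet(cfg.dm_concentration * alpha[alive]
                                    / alpha[alive].sum())
        depth = rng.poisson(cfg.depth_mean)
        counts[hen] = rng.multinomial(depth, comp)

    count_df = pd.DataFrame(counts, index=asv_ids).T  # samples x ASVs
    taxonomy = pd.Series([_lineage_string(MOCK_LINEAGES[i]) for i in lin_idx],
                         index=asv_ids, name="taxonomy")
    return AsvTable(counts=count_df, taxonomy=taxonomy,
                    groups=groups.astype(str))


def generate_all(cfg: SynthConfig) -> dict:
    """Generate the full synthetic study bundle keyed by data stream."""
    from . import rank as rank_mod

    profiles = make_profiles(cfg)
    competition = generate_competition(profiles, cfg)
    rank_table = rank_mod.build_rank_table(competition)
    events = generate_feeder_events(rank_table, cfg)
    weights = generate_body_weights(rank_table, cfg)
    final_w = (weights.sort_values("date").groupby("hen")["weight_g"].last())
    organs = generate_organs(rank_table, cfg, final_weights=final_w)
    hrlr = rank_table.loc[rank_table["group"].isin(["HR", "LR"]), "group"]
    vig = generate_vigilance(hrlr, cfg=cfg)
    asv = generate_asv_table(hrlr, cfg)
    return {"profiles": profiles, "competition": competition,
            "rank_table": rank_table, "feeder_events": events,
            "body_weights": weights, "organs": organs,
            "vigilance": vig, "asv_table": asv}


def write_dataset(bundle: dict, outdir) -> dict:
    """Write every stream of a bundle as TSV/CSV; returns name -> path."""
    from pathlib import Path

    from .microbiome import write_asv_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _w(name, df, sep="\t", index=False):
        ext = "csv" if sep == "," else "tsv"
        p = outdir / f"{name}.{ext}"
        df.to_csv(p, sep=sep, index=index)
        paths[name] = p

    _w("profiles", bundle["profiles"].reset_index())
    _w("competition", bundle["competition"])
    _w("rank_table", bundle["rank_table"].reset_index())
    _w("feeder_events", bundle["feeder_events"], sep=",")
    _w("body_weights", bundle["body_weights"])
    _w("organs", bundle["organs"])
    _w("vigilance", bundle["vigilance"])
    paths["asv_table"] = outdir / "asv_table.tsv"
    write_asv_table(bundle["asv_table"], paths["asv_table"])
    groups = bundle["asv_table"].groups
    _w("groups", groups.rename("group").rename_axis("hen").reset_index())
    return paths
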