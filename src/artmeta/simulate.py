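"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates (i) effect-size tables drawn from the multilevel
meta-analytic model — crossed phylogeny/species/study/observation random
effects, within-experiment correlated sampling errors, categorical and
continuous moderators — and (ii) raw log-linear testes allometry tables per
tactic, the input of the GSI-vs-ANCOVA comparison.  A single integer seed
fixes every stream; serialization uses fixed-precision text so identical
seeds give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .allometry import AllometryTable
from .meta import EFFECT_COLUMNS, MetaDataset
from .phylo import as_newick, grafen_transform, unit_branch_lengths, vcv_from_tree

__all__ = [
    "SimulationConfig",
    "AllometrySimConfig",
    "simulate_tree",
    "simulate_effects",
    "simulate_allometry",
    "write_fixtures",
]

_TRAIT_MEASURES = {
    "testes_size": ("GSI", "relative_testes"),
    "sperm_quantity": ("sperm_number", "sperm_density", "sperm_volume"),
    "sperm_trait": ("length", "speed", "longevity", "atp", "motile_viable"),
}


@dataclass
class AllometrySimConfig:
    """Raw-morphometry generator: log(testes) = log(a) + shift*[high tactic]
    + slope*log(body) + N(0, noise_sd^2).

    Defaults are the negative-allometry benchmark: slope 0.5, two-fold
    body-size dimorphism (guarders larger), no intercept difference, 30
    individuals per tactic, ~10% multiplicative noise.
    """

    slope: float = 0.5
    intercept: float = 0.1  # scale coefficient a (mass units)
    tactic_effect: float = 0.0  # log-scale intercept shift for the high-risk tactic
    dimorphism: float = 2.0  # mean body mass ratio, low-risk over high-risk tactic
    noise_sd: float = 0.1
    n_per_tactic: int = 30
    body_mean: float = 20.0  # mean body mass of the high-risk (smaller) tactic
    body_cv: float = 0.15  # log-scale SD of body mass within a tactic
    tactics: tuple[str, str] = ("guarder", "sneaker")  # (low-risk, high-risk)


@dataclass
class SimulationConfig:
    """True model parameters and design layout for simulated effect sizes.

    ``beta`` is the grand mean on the d scale; ``sigma2`` the true variance
    components for the phylogeny / species / study / observation factors;
    ``rho_true`` the correlation of sampling errors within an experiment;
    sampling variances are uniform on ``v_range``.
    """

    seed: int = 0
    n_species: int = 67
    n_effects: int | None = None  # exact total; None = one pass over species
    studies_per_species: tuple[int, int] = (1, 2)
    effects_per_study: tuple[int, int] = (1, 4)
    max_experiment_size: int = 3
    beta: float = 0.4
    sigma2: dict[str, float] = field(
        default_factory=lambda: {
            "phylogeny": 0.2,
            "species": 0.1,
            "study": 0.1,
            "observation": 0.05,
        }
    )
    rho_true: float = 0.5
    v_range: tuple[float, float] = (0.05, 0.5)
    moderator_effects: dict = field(default_factory=dict)
    taxon_props: dict[str, float] = field(
        default_factory=lambda: {"fish": 0.6, "invertebrate": 0.25, "other_vertebrate": 0.15}
    )
    fert_props: dict[str, float] = field(
        default_factory=lambda: {"external": 0.7, "internal": 0.3}
    )
    tactic_props: dict[str, float] = field(
        default_factory=lambda: {"fixed": 0.3, "state_dependent": 0.6, "plastic": 0.1}
    )
    trait_props: dict[str, float] = field(
        default_factory=lambda: {"testes_size": 0.3, "sperm_quantity": 0.2, "sperm_trait": 0.5}
    )
    sneaker_freq_beta: tuple[float, float] = (2.0, 5.0)
    year_range: tuple[int, int] = (1990, 2020)
    directionless_prob: float = 0.0
    censor_prob: float = 0.0  # small-study censoring for bias simulations
    censor_v_threshold: float = 0.2
    allometry: AllometrySimConfig = field(default_factory=AllometrySimConfig)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma2.values()):
            raise ValueError("variance components must be nonnegative")
        if not 0.0 <= self.rho_true < 1.0:
            raise ValueError("rho_true must lie in [0, 1)")


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) topology, unit branch lengths, Grafen-ultrametric."""
    if n_species < 2:
        raise ValueError("need at least two species")
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=random.Random(int(seed)),
    )
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:03d}"
    return grafen_transform(unit_branch_lengths(tree))


def _choose(rng, props: dict[str, float], size: int) -> np.ndarray:
    names = list(props)
    p = np.array([props[n] for n in names], dtype=float)
    return rng.choice(names, size=size, p=p / p.sum())


def simulate_effects(config: SimulationConfig, tree: dendropy.Tree) -> MetaDataset:
    """Draw a MetaDataset from the multilevel model.

    y_i = beta + moderator effects + a_sp (phylo-correlated) + b_sp + c_study
    + e_obs + eps_i, with eps correlated at rho_true within experiments and
    var(eps_i) = v_i ~ U(v_range).
    """
    rng = np.random.default_rng(config.seed)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if config.n_species > len(species):
        raise ValueError("tree has fewer tips than n_species")
    species = species[: config.n_species]

    # design layout: species -> studies -> experiments -> effects
    rows = []
    study_no = 0
    done = False
    while not done:
        for sp in species:
            n_studies = int(rng.integers(*config.studies_per_species, endpoint=True))
            for _ in range(n_studies):
                study_no += 1
                study = f"study{study_no:04d}"
                year = int(rng.integers(*config.year_range, endpoint=True))
                n_eff = int(rng.integers(*config.effects_per_study, endpoint=True))
                exp_no = 0
                left = n_eff
                while left > 0:
                    exp_no += 1
                    m = int(min(left, rng.integers(1, config.max_experiment_size, endpoint=True)))
                    for _ in range(m):
                        rows.append((sp, study, f"{study}_e{exp_no}", year))
                    left -= m
                if config.n_effects is not None and len(rows) >= config.n_effects:
                    done = True
                    break
            if done:
                break
        if config.n_effects is None:
            done = True
    if config.n_effects is not None:
        rows = rows[: config.n_effects]
    k = len(rows)
    df = pd.DataFrame(rows, columns=["species", "study_id", "experiment_id", "pub_year"])
    df["observation_id"] = [f"obs{i + 1:04d}" for i in range(k)]

    # species-level attributes
    used = sorted(df["species"].unique())
    sp_attr = pd.DataFrame(
        {
            "species": used,
            "taxon_group": _choose(rng, config.taxon_props, len(used)),
            "fert_mode": _choose(rng, config.fert_props, len(used)),
            "tactic_type": _choose(rng, config.tactic_props, len(used)),
            "sneaker_freq": rng.beta(*config.sneaker_freq_beta, size=len(used)),
        }
    )
    df = df.merge(sp_attr, on="species", how="left")
    df["trait_category"] = _choose(rng, config.trait_props, k)
    df["measurement"] = [
        _TRAIT_MEASURES[cat][rng.integers(0, len(_TRAIT_MEASURES[cat]))]
        for cat in df["trait_category"]
    ]

    # random effects
    corr = vcv_from_tree(tree).submatrix(used)
    chol = np.linalg.cholesky(corr.matrix + 1e-10 * np.eye(len(used)))
    a = np.sqrt(config.sigma2["phylogeny"]) * (chol @ rng.standard_normal(len(used)))
    b = np.sqrt(config.sigma2["species"]) * rng.standard_normal(len(used))
    sp_index = {s: i for i, s in enumerate(used)}
    studies = sorted(df["study_id"].unique())
    c = np.sqrt(config.sigma2["study"]) * rng.standard_normal(len(studies))
    st_index = {s: i for i, s in enumerate(studies)}
    e = np.sqrt(config.sigma2["observation"]) * rng.standard_normal(k)

    v = rng.uniform(*config.v_range, size=k)
    eps = np.empty(k)
    for _, idx in df.groupby("experiment_id").groups.items():
        idx = np.asarray(idx)
        m = len(idx)
        if m == 1:
            z = rng.standard_normal(1)
        else:
            r = np.full((m, m), config.rho_true)
            np.fill_diagonal(r, 1.0)
            z = np.linalg.cholesky(r) @ rng.standard_normal(m)
        eps[idx] = np.sqrt(v[idx]) * z

    mu = np.full(k, config.beta)
    for col, effect in config.moderator_effects.items():
        if isinstance(effect, dict):
            mu += df[col].map(effect).fillna(0.0).to_numpy(dtype=float)
        else:
            mu += float(effect) * df[col].to_numpy(dtype=float)

    y = (
        mu
        + a[[sp_index[s] for s in df["species"]]]
        + b[[sp_index[s] for s in df["species"]]]
        + c[[st_index[s] for s in df["study_id"]]]
        + e
        + eps
    )
    df["d"] = y
    df["var"] = v
    df["directionless"] = rng.random(k) < config.directionless_prob
    df.loc[df["directionless"], "d"] = 0.0

    if config.censor_prob > 0:
        drop = (
            (df["d"] < 0)
            & (df["var"] > config.censor_v_threshold)
            & (rng.random(k) < config.censor_prob)
        )
        df = df.loc[~drop].reset_index(drop=True)

    return MetaDataset(df[EFFECT_COLUMNS], tree=tree, rho=config.rho_true)


def simulate_allometry(
    config: AllometrySimConfig,
    seed: int = 0,
    study_id: str = "study0001",
    species: str = "sp001",
) -> AllometryTable:
    """One raw testes/body table under log-linear allometry per tactic."""
    if config.slope <= 0:
        raise ValueError("allometric slope must be positive")
    rng = np.random.default_rng(seed)
    low, high = config.tactics
    rows = []
    means = {high: config.body_mean, low: config.body_mean * config.dimorphism}
    shifts = {high: config.tactic_effect, low: 0.0}
    i = 0
    for tactic in (low, high):
        body = np.exp(
            np.log(means[tactic]) + config.body_cv * rng.standard_normal(config.n_per_tactic)
        )
        log_testes = (
            np.log(config.intercept)
            + shifts[tactic]
            + config.slope * np.log(body)
            + config.noise_sd * rng.standard_normal(config.n_per_tactic)
        )
        testes = np.exp(log_testes)
        if np.any(testes >= body):
            raise ValueError("allometry parameters yield testes mass >= body mass")
        for bm, tm in zip(body, testes):
            i += 1
            rows.append((f"ind{i:03d}", tactic, float(bm), float(tm)))
    data = pd.DataFrame(rows, columns=["individual_id", "tactic", "body_mass", "testes_mass"])
    return AllometryTable(data, study_id=study_id, species=species)


def write_fixtures(output_dir, config: SimulationConfig, n_allometry_tables: int = 5):
    """Emit effects.csv, tree.nwk, allometry/*.csv and manifest.json.

    Regenerating with the manifest's seed reproduces the files byte for byte.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config.n_species, config.seed)
    dataset = simulate_effects(config, tree)

    eff = dataset.effects.copy()
    for col in ("d", "var", "sneaker_freq"):
        eff[col] = eff[col].map(lambda x: f"{x:.10g}")
    effects_path = out / "effects.csv"
    eff.to_csv(effects_path, index=False)
    tree_path = out / "tree.nwk"
    tree_path.write_text(as_newick(tree))

    allo_dir = out / "allometry"
    allo_dir.mkdir(exist_ok=True)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    paths = []
    for j in range(n_allometry_tables):
        table = simulate_allometry(
            config.allometry,
            seed=config.seed + 1000 + j,
            study_id=f"allo{j + 1:03d}",
            species=species[j % len(species)],
        )
        data = table.data.copy()
        for col in ("body_mass", "testes_mass"):
            data[col] = data[col].map(lambda x: f"{x:.10g}")
        path = allo_dir / f"{table.study_id}.csv"
        data.to_csv(path, index=False)
        paths.append(str(path))

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "files": {
            "effects": str(effects_path),
            "tree": str(tree_path),
            "allometry": paths,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
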