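"""Synthetic phylogenies, traits, habitat grids and occurrence records.

The generator emulates the data structure of a continental-scale bee
comparative study: an ultrametric species phylogeny, specimen measurements
of brain mass (mg) and intertegular span (mm) that follow a log-log
allometry with phylogenetically correlated residuals, a categorical
land-cover grid reclassified into natural / agricultural / urban, and
georeferenced occurrence records whose habitat mix can be coupled to
relative brain size.  The coupling parameter ``gamma`` shifts a species'
urban log-odds by ``gamma`` per unit of allometric residual, implementing
the hypothesis under test; ``gamma = 0`` gives the matching null scenario.

All stages are deterministic per seed: the scenario seed is split into
independent substreams for tree, traits, grid and records.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._gls import lambda_cov
from .occupancy import HABITATS, HabitatGrid
from .phylo import PhyloTree, phylo_covariance, read_newick

__all__ = [
    "ScenarioConfig",
    "ScenarioBundle",
    "spawn_seeds",
    "simulate_tree",
    "simulate_allometric_traits",
    "simulate_grid",
    "simulate_occurrence_records",
    "make_scenario",
]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


@dataclass
class ScenarioConfig:
    """Generating parameters for one synthetic study.

    Defaults mirror the structure of the empirical setting the pipeline is
    built for: on the order of 10^2 species, a log-log brain-body allometry
    with slope 2.5 and phylogenetically correlated residuals (lambda 0.6),
    overdispersed per-species record counts with at least 50 records, a
    landscape dominated by natural cover with urban rarest, and collection
    years 1990-2022 printed at four coordinate decimals.
    """

    n_species: int = 150
    seed: int = 0
    # tree
    tree_model: str = "yule"  # or "birth_death"
    birth_rate: float = 1.0
    death_rate: float = 0.0
    # allometry (log-log, natural logs)
    intercept: float = -3.0
    slope: float = 2.5
    lambda_true: float = 0.6
    sigma_resid: float = 0.33
    body_mean: float = 0.7  # ln(mm); exp ~ 2 mm intertegular span
    body_sigma: float = 0.4  # Brownian-motion sd at the tips (depth-1 tree)
    # coupling of allometric residual to urban log-odds
    gamma: float = 1.5
    # records
    records_mean: float = 120.0
    records_dispersion: float = 5.0  # negative-binomial size parameter
    enforce_min_records: bool = True
    min_records: int = 50
    year_range: tuple[int, int] = (1990, 2022)
    coord_decimals: int = 4
    # grid
    grid_rows: int = 30
    grid_cols: int = 30
    class_mixture: tuple[float, float, float] = (0.5, 0.3, 0.2)
    lat_min: float = 40.0
    lat_max: float = 43.0
    lon_min: float = 0.0
    lon_max: float = 3.0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("birth rate must be > 0 and death rate >= 0")
        if self.tree_model not in ("yule", "birth_death"):
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if not np.isclose(sum(self.class_mixture), 1.0):
            raise ValueError("class mixture must sum to 1")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["year_range"] = list(self.year_range)
        d["class_mixture"] = list(self.class_mixture)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "year_range" in d:
            d["year_range"] = tuple(d["year_range"])
        if "class_mixture" in d:
            d["class_mixture"] = tuple(d["class_mixture"])
        return cls(**d)


def simulate_tree(
    n_species: int,
    *,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
) -> PhyloTree:
    """Ultrametric birth-death (or Yule) tree scaled to unit depth.

    Tips are relabelled ``sp001 ...`` in a fixed order so the same seed
    always yields byte-identical Newick output.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if birth_rate <= 0 or death_rate < 0:
        raise ValueError("invalid birth/death rates")
    if n_species == 2:
        return read_newick("(sp001:1.0,sp002:1.0);")
    from dendropy.simulate import treesim

    rng = _random.Random(seed)
    tree = None
    for _ in range(20):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=birth_rate,
                death_rate=death_rate,
                num_extant_tips=n_species,
                rng=rng,
            )
            break
        except Exception:
            continue
    if tree is None:
        raise RuntimeError("birth-death simulation failed repeatedly")
    # deterministic relabelling in leaf-iteration order
    ns = dendropy.TaxonNamespace()
    width = max(3, len(str(n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(label=f"sp{i:0{width}d}")
    tree.taxon_namespace = ns
    # scale to unit depth
    depths = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = 0.0
        else:
            depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    max_depth = max(depths[lf] for lf in tree.leaf_node_iter())
    if max_depth <= 0:
        raise RuntimeError("degenerate simulated tree")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is not None:
            nd.edge.length /= max_depth
    # round-trip through Newick so equal seeds give identical strings
    return read_newick(
        tree.as_string(schema="newick", suppress_rooting=True).strip()
    )


def simulate_allometric_traits(
    tree: PhyloTree,
    *,
    intercept: float = -3.0,
    slope: float = 2.5,
    lambda_true: float = 0.6,
    sigma_resid: float = 0.33,
    body_mean: float = 0.7,
    body_sigma: float = 0.4,
    region_probs: tuple[float, float, float] = (0.45, 0.45, 0.1),
    seed: int = 0,
) -> pd.DataFrame:
    """Specimen table (one specimen per species) from a phylogenetic model.

    Log body size evolves by Brownian motion on the tree (sd ``body_sigma``
    at unit depth); log brain mass is ``intercept + slope * log_body`` plus
    a residual with covariance ``sigma_resid^2 * V(lambda_true)``.  Regions
    (US / EU / both) are assigned independently per species.
    """
    rng = np.random.default_rng(seed)
    V = phylo_covariance(tree)
    n = V.n
    Lb = np.linalg.cholesky(V.values + 1e-12 * np.eye(n))
    log_body = body_mean + body_sigma * (Lb @ rng.standard_normal(n))
    if sigma_resid > 0:
        Vl = lambda_cov(V.values, lambda_true)
        Lr = np.linalg.cholesky(Vl + 1e-12 * np.eye(n))
        resid = sigma_resid * (Lr @ rng.standard_normal(n))
    else:
        resid = np.zeros(n)
    log_brain = intercept + slope * log_body + resid
    region = rng.choice(["US", "EU", "both"], size=n, p=region_probs)
    return pd.DataFrame(
        {
            "species": V.labels,
            "brain_mg": np.exp(log_brain),
            "itd_mm": np.exp(log_body),
            "region": region,
            "residual_true": resid,
        }
    )


def simulate_grid(config: ScenarioConfig, seed: int) -> HabitatGrid:
    """Random categorical grid with the configured habitat-class mixture.

    Two raw cover codes feed each habitat class so the reclassification
    step is exercised (codes 2k and 2k+1 both map to class k).
    """
    rng = np.random.default_rng(seed)
    classes = rng.choice(
        3, size=(config.grid_rows, config.grid_cols), p=list(config.class_mixture)
    )
    subcode = rng.integers(0, 2, size=classes.shape)
    codes = 2 * classes + subcode
    reclass = {2 * k + s: HABITATS[k] for k in range(3) for s in (0, 1)}
    grid = HabitatGrid(
        codes=codes,
        lat_min=config.lat_min,
        lat_max=config.lat_max,
        lon_min=config.lon_min,
        lon_max=config.lon_max,
        reclass=reclass,
    )
    present = set(grid.class_grid().ravel().tolist())
    if present != set(HABITATS):
        # tiny grids can miss a rare class by chance; force one cell of each
        flat = codes.ravel()
        for k, hab in enumerate(HABITATS):
            if hab not in present:
                flat[int(rng.integers(0, flat.size))] = 2 * k
        grid = HabitatGrid(
            codes=flat.reshape(codes.shape),
            lat_min=config.lat_min,
            lat_max=config.lat_max,
            lon_min=config.lon_min,
            lon_max=config.lon_max,
            reclass=reclass,
        )
    return grid


def simulate_occurrence_records(
    species: list[str],
    residuals: np.ndarray | pd.Series,
    config: ScenarioConfig,
    grid: HabitatGrid,
    seed: int,
) -> pd.DataFrame:
    """Georeferenced records with residual-coupled urban affinity.

    Habitat-class probabilities per species are a softmax of the base
    log-odds (log of the grid class mixture) with ``gamma * residual``
    added to the urban component only.  Each record lands uniformly inside
    a uniformly chosen cell of its class; years are uniform in the
    configured range and coordinates are printed with a fixed number of
    decimals (>= 2).
    """
    rng = np.random.default_rng(seed)
    resid = np.asarray(residuals, dtype=float)
    if len(resid) != len(species):
        raise ValueError("one residual per species is required")
    class_grid = grid.class_grid()
    cells_by_class = {
        hab: np.argwhere(class_grid == hab) for hab in HABITATS
    }
    base_logodds = np.log(np.asarray(config.class_mixture, dtype=float))
    urban_idx = HABITATS.index("urban")
    for hab in HABITATS:
        if len(cells_by_class[hab]) == 0 and config.class_mixture[HABITATS.index(hab)] > 0:
            raise ValueError(f"grid has no {hab!r} cell but its probability is > 0")

    fmt = f"{{:.{config.coord_decimals}f}}"
    y0, y1 = config.year_range
    rows: list[tuple] = []
    p_nb = config.records_dispersion / (config.records_dispersion + config.records_mean)
    for sp, r in zip(species, resid):
        count = int(rng.negative_binomial(config.records_dispersion, p_nb))
        if config.enforce_min_records:
            count = max(count, config.min_records)
        count = max(count, 1)
        logits = base_logodds.copy()
        logits[urban_idx] += config.gamma * r
        p = np.exp(logits - logits.max())
        p /= p.sum()
        counts = rng.multinomial(count, p)
        for hab, k in zip(HABITATS, counts):
            if k == 0:
                continue
            cells = cells_by_class[hab]
            pick = cells[rng.integers(0, len(cells), size=k)]
            dlat = rng.random(k)
            dlon = rng.random(k)
            lat = grid.lat_min + (pick[:, 0] + dlat) * grid.cell_height
            lon = grid.lon_min + (pick[:, 1] + dlon) * grid.cell_width
            years = rng.integers(y0, y1 + 1, size=k)
            for la, lo, yr in zip(lat, lon, years):
                lat_text = fmt.format(la)
                lon_text = fmt.format(lo)
                rows.append((sp, float(lat_text), float(lon_text), int(yr), lat_text, lon_text))
    df = pd.DataFrame(
        rows, columns=["species", "lat", "lon", "year", "lat_text", "lon_text"]
    )
    return df


@dataclass
class ScenarioBundle:
    """A complete synthetic dataset plus its generating truth."""

    tree: PhyloTree
    specimens: pd.DataFrame
    records: pd.DataFrame
    grid: HabitatGrid
    truth: dict = field(default_factory=dict)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        self.specimens.to_csv(directory / "specimens.csv", index=False)
        self.records.to_csv(directory / "records.csv", index=False)
        self.grid.save(directory / "grid")
        (directory / "truth.json").write_text(json.dumps(self.truth, indent=2))
        manifest = {
            "tree": "tree.nwk",
            "specimens": "specimens.csv",
            "records": "records.csv",
            "grid": "grid",
            "truth": "truth.json",
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ScenarioBundle":
        directory = Path(directory)
        tree = read_newick((directory / "tree.nwk").read_text())
        specimens = pd.read_csv(directory / "specimens.csv")
        records = pd.read_csv(
            directory / "records.csv", dtype={"lat_text": str, "lon_text": str}
        )
        grid = HabitatGrid.load(directory / "grid")
        truth = json.loads((directory / "truth.json").read_text())
        return cls(tree=tree, specimens=specimens, records=records, grid=grid, truth=truth)


def make_scenario(config: ScenarioConfig, out_dir=None) -> ScenarioBundle:
    """Compose tree, traits, grid and records into one reproducible bundle."""
    tree_seed, trait_seed, grid_seed, rec_seed = spawn_seeds(config.seed, 4)
    death = config.death_rate if config.tree_model == "birth_death" else 0.0
    tree = simulate_tree(
        config.n_species,
        birth_rate=config.birth_rate,
        death_rate=death,
        seed=tree_seed,
    )
    specimens = simulate_allometric_traits(
        tree,
        intercept=config.intercept,
        slope=config.slope,
        lambda_true=config.lambda_true,
        sigma_resid=config.sigma_resid,
        body_mean=config.body_mean,
        body_sigma=config.body_sigma,
        seed=trait_seed,
    )
    grid = simulate_grid(config, grid_seed)
    records = simulate_occurrence_records(
        list(specimens["species"]),
        specimens["residual_true"].to_numpy(),
        config,
        grid,
        rec_seed,
    )
    truth = {
        "config": config.to_dict(),
        "substream_seeds": {
            "tree": tree_seed,
            "traits": trait_seed,
            "grid": grid_seed,
            "records": rec_seed,
        },
        "residual_true": {
            sp: float(r)
            for sp, r in zip(specimens["species"], specimens["residual_true"])
        },
    }
    bundle = ScenarioBundle(
        tree=tree,
        specimens=specimens.drop(columns=["residual_true"]),
        records=records,
        grid=grid,
        truth=truth,
    )
    if out_dir is not None:
        bundle.save(out_dir)
    return bundle
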