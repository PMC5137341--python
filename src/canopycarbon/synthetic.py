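"""Synthetic conifer-forest generator.

Emulates the statistical structure the pipeline assumes so every stage is
testable at desk scale without field data: an Alpine-type stand (stem
diameters 3.5-121 cm, heights 1.5-48.8 m, crown areas 1.5-55.4 m2, 5+
species), a ~48 pts/m2 laser point cloud with up to 4 returns, Gaussian-
class hyperspectral pixels with a configurable target class separability,
and field-inventory plots (fixed-radius or angle-count) with realistic
measurement error (DBH 1.5%, height 5%).

Trees are placed by a Poisson process with hard-core inhibition (minimum
spacing proportional to crown radius).  Crowns are paraboloids of
revolution — the simplest surface with a unique apex that region growing
can segment.  Heights and crown areas are drawn first and stem diameter
follows the ground-truth DBH model with multiplicative lognormal scatter,
so refitting the model recovers the truth coefficients.  Understorey trees
are tucked beneath dominant crowns until they hold a prescribed share of
stand carbon, giving the hidden-tree correction multiplier a known truth
value of ``1 / (1 - share)``.

Everything is driven by one integer seed; a fixed seed reproduces the
forest, cloud, cube and inventory exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import AgbCoefficients, DbhCoefficients, agb_tree, carbon_tree, dbh_model
from .io_formats import HyperCube, PointCloud
from .matching_eval import Plot, bitterlich_included


@dataclass
class ForestScenario:
    """Study conditions for the synthetic stand."""

    extent_m: float = 100.0
    stems_per_ha: float = 500.0
    species_mix: dict = field(default_factory=lambda: {
        "Picea abies": 0.50, "Larix decidua": 0.20, "Abies alba": 0.15,
        "Pinus cembra": 0.10, "Angiosperms": 0.05})
    species_group: dict = field(default_factory=lambda: {
        "Picea abies": "conifer", "Larix decidua": "conifer",
        "Abies alba": "conifer", "Pinus cembra": "conifer",
        "Angiosperms": "angiosperm"})
    # height distribution (lognormal, m) and admissible ranges
    height_meanlog: float = np.log(24.0)
    height_sdlog: float = 0.32
    height_range: tuple = (1.5, 48.8)
    dbh_range: tuple = (3.5, 121.0)
    crown_area_range: tuple = (1.5, 55.4)
    crown_radius_per_height: float = 0.11   # crown radius ~ ratio * H
    crown_base_frac: float = 0.5            # crown base at frac * H
    dbh_noise_cv: float = 0.15              # lognormal scatter of DBH around model
    hidden_carbon_share: float = 0.19       # carbon share of below-cut-off trees
    understorey_height_range: tuple = (3.0, 9.0)
    min_spacing_factor: float = 0.6         # hard-core radius = factor * crown radius
    grid_placement: bool = False            # regular jittered grid instead of Poisson
    grid_spacing_m: float = 8.0
    pulse_density: float = 48.0             # pts/m2
    vertical_noise_sd: float = 0.1          # m
    penetration_prob: float = 0.3           # chance a canopy pulse yields extra returns
    # hyperspectral regime
    n_bands: int = 20
    target_jm: float = 1.9
    spectral_noise_sd: float = 0.01
    shading_factor: float = 0.6             # brightness multiplier at crown edges
    shaded_edge_frac: float = 0.75          # pixels with d/r above this are shaded
    cube_resolution: float = 1.0
    # measurement error
    dbh_measure_cv: float = 0.015
    height_measure_cv: float = 0.05
    seed: int = 0
    dbh_truth: DbhCoefficients | None = None
    agb_truth: AgbCoefficients | None = None

    def __post_init__(self) -> None:
        mix = sum(self.species_mix.values())
        if not np.isclose(mix, 1.0):
            raise ValueError("species mixture proportions must sum to 1")
        if self.pulse_density <= 0:
            raise ValueError("pulse_density must be positive")
        if self.dbh_truth is None:
            self.dbh_truth = DbhCoefficients.packaged_alpine()
        if self.agb_truth is None:
            self.agb_truth = AgbCoefficients.packaged_synthetic()


def alpine_default(seed: int = 0) -> ForestScenario:
    """Mixed Alpine conifer stand with a hidden understorey (default conditions)."""
    return ForestScenario(seed=seed)


def separable_stand(seed: int = 0) -> ForestScenario:
    """Non-overlapping crowns on a jittered grid; every tree is detectable."""
    return ForestScenario(
        extent_m=80.0, grid_placement=True, grid_spacing_m=8.0,
        height_meanlog=np.log(22.0), height_sdlog=0.15,
        height_range=(15.0, 35.0), crown_radius_per_height=0.10,
        hidden_carbon_share=0.0, vertical_noise_sd=0.05, seed=seed)


def null_spectra(seed: int = 0) -> ForestScenario:
    """Spectrally indistinguishable species (target JM ~ 0)."""
    return ForestScenario(target_jm=1e-3, seed=seed)


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------


def _truth_row(scenario: ForestScenario, species: str):
    return scenario.dbh_truth.row(species)


def _tree_record(scenario: ForestScenario, rng, tid, x, y, h, species,
                 understorey=False) -> dict:
    r_crown = scenario.crown_radius_per_height * h
    ca = np.pi * r_crown ** 2
    lo, hi = scenario.crown_area_range
    ca = float(np.clip(ca, lo, hi))
    r_crown = float(np.sqrt(ca / np.pi))
    row = _truth_row(scenario, species)
    noise = np.exp(rng.normal(0.0, scenario.dbh_noise_cv))
    dbh = float(dbh_model(h, ca, row["epsilon"], row["rho"], row["theta"]) * noise)
    dbh = float(np.clip(dbh, *scenario.dbh_range))
    agb = agb_tree(dbh, h, scenario.agb_truth, species)
    group = scenario.species_group.get(species, "conifer")
    carbon = carbon_tree(agb, group)
    return {"id": tid, "x": x, "y": y, "species": species, "group": group,
            "height_m": h, "crown_radius_m": r_crown, "crown_area_m2": ca,
            "dbh_cm": dbh, "agb_kg": agb, "carbon_kg": carbon,
            "understorey": understorey}


def simulate_forest(scenario: ForestScenario) -> pd.DataFrame:
    """Generate the ground-truth stem table (one row per tree).

    Overstorey trees are placed by hard-core-inhibited Poisson darts (or a
    jittered grid); understorey trees are added beneath random overstorey
    crowns until they hold ``hidden_carbon_share`` of total carbon.
    """
    rng = np.random.default_rng(scenario.seed)
    ext = scenario.extent_m
    species = list(scenario.species_mix)
    probs = np.array([scenario.species_mix[s] for s in species])
    records: list[dict] = []
    tid = 1

    if scenario.grid_placement:
        sp = scenario.grid_spacing_m
        n_side = int(ext // sp)
        for i in range(n_side):
            for j in range(n_side):
                x = (i + 0.5) * sp + rng.uniform(-0.1 * sp, 0.1 * sp)
                y = (j + 0.5) * sp + rng.uniform(-0.1 * sp, 0.1 * sp)
                h = float(np.clip(rng.lognormal(scenario.height_meanlog,
                                                scenario.height_sdlog),
                                  *scenario.height_range))
                s = species[rng.choice(len(species), p=probs)]
                records.append(_tree_record(scenario, rng, tid, x, y, h, s))
                tid += 1
    else:
        n_target = rng.poisson(scenario.stems_per_ha * ext * ext / 10_000.0)
        placed_xy: list[tuple[float, float, float]] = []   # x, y, hardcore radius
        attempts = 0
        while len(placed_xy) < n_target and attempts < 50 * max(n_target, 1):
            attempts += 1
            x, y = rng.uniform(0, ext, 2)
            h = float(np.clip(rng.lognormal(scenario.height_meanlog,
                                            scenario.height_sdlog),
                              *scenario.height_range))
            r_hc = scenario.min_spacing_factor * scenario.crown_radius_per_height * h
            ok = all((x - px) ** 2 + (y - py) ** 2 >= (r_hc + pr) ** 2
                     for px, py, pr in placed_xy)
            if not ok:
                continue
            placed_xy.append((x, y, r_hc))
            s = species[rng.choice(len(species), p=probs)]
            records.append(_tree_record(scenario, rng, tid, x, y, h, s))
            tid += 1
        if n_target > 0 and not records:
            raise RuntimeError("infeasible density/spacing: no tree could be placed")

    df = pd.DataFrame(records)
    share = scenario.hidden_carbon_share
    if share > 0 and len(df):
        over_carbon = df["carbon_kg"].sum()
        target_under = share / (1.0 - share) * over_carbon
        acc = 0.0
        under: list[dict] = []
        while acc < target_under:
            host = df.iloc[int(rng.integers(0, len(df)))]
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, host["crown_radius_m"])
            x = float(np.clip(host["x"] + rad * np.cos(ang), 0, ext))
            y = float(np.clip(host["y"] + rad * np.sin(ang), 0, ext))
            h = float(rng.uniform(*scenario.understorey_height_range))
            s = species[rng.choice(len(species), p=probs)]
            rec = _tree_record(scenario, rng, tid, x, y, h, s, understorey=True)
            under.append(rec)
            acc += rec["carbon_kg"]
            tid += 1
        df = pd.concat([df, pd.DataFrame(under)], ignore_index=True)
    return df


def simulate_dbh_triples(n: int, epsilon: float, rho: float, theta: float,
                         noise_cv: float = 0.15, seed: int = 0,
                         height_range=(5.0, 45.0), ca_range=(1.5, 55.0)):
    """(H, CA, DBH) triples from the DBH model with lognormal scatter.

    The generating coefficients are the truth the fitting routine should
    recover.  Heights and crown areas are uniform over their ranges.
    """
    rng = np.random.default_rng(seed)
    h = rng.uniform(*height_range, n)
    ca = rng.uniform(*ca_range, n)
    dbh = dbh_model(h, ca, epsilon, rho, theta) * np.exp(rng.normal(0, noise_cv, n))
    return h, ca, dbh


# ---------------------------------------------------------------------------
# point cloud
# ---------------------------------------------------------------------------


def _crown_surface(df: pd.DataFrame, px: np.ndarray, py: np.ndarray,
                   base_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Highest paraboloid crown surface above each (px, py); 0 where open ground.

    Returns (surface height, index of intercepting tree or -1).
    """
    z = np.zeros(px.size)
    owner = np.full(px.size, -1)
    for i, t in df.iterrows():
        r = t["crown_radius_m"]
        d2 = (px - t["x"]) ** 2 + (py - t["y"]) ** 2
        m = d2 < r * r
        if not m.any():
            continue
        apex = t["height_m"]
        base = base_frac * apex
        surf = apex - (apex - base) * d2[m] / (r * r)
        upd = surf > z[m]
        zi = z[m]; oi = owner[m]
        zi[upd] = surf[upd]; oi[upd] = i
        z[m] = zi; owner[m] = oi
    return z, owner


def simulate_point_cloud(forest: pd.DataFrame,
                         scenario: ForestScenario) -> PointCloud:
    """Laser returns over the stand: jittered pulse grid at ``pulse_density``.

    The first return of each pulse samples the tallest intercepting crown
    surface plus Gaussian noise; open-ground pulses return near 0.  A
    fraction of canopy pulses penetrates, adding up to 3 deeper returns.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    ext = scenario.extent_m
    spacing = 1.0 / np.sqrt(scenario.pulse_density)
    n_side = int(np.round(ext / spacing))
    gx, gy = np.meshgrid((np.arange(n_side) + 0.5) * spacing,
                         (np.arange(n_side) + 0.5) * spacing)
    px = (gx + rng.uniform(-0.4 * spacing, 0.4 * spacing, gx.shape)).ravel()
    py = (gy + rng.uniform(-0.4 * spacing, 0.4 * spacing, gy.shape)).ravel()
    px = np.clip(px, 0, ext - 1e-9)
    py = np.clip(py, 0, ext - 1e-9)

    surf, owner = _crown_surface(forest, px, py, scenario.crown_base_frac)
    noise = rng.normal(0, scenario.vertical_noise_sd, px.size)
    z1 = np.where(owner >= 0, surf + noise, np.abs(noise))
    z1 = np.maximum(z1, 0.0)

    xs = [px]; ys = [py]; zs = [z1]
    rns = [np.ones(px.size, dtype=int)]
    grounds = [owner < 0]
    n_extra = np.zeros(px.size, dtype=int)
    canopy = owner >= 0
    pen = canopy & (rng.random(px.size) < scenario.penetration_prob)
    n_extra[pen] = rng.integers(1, 4, int(pen.sum()))
    for k in range(1, 4):
        m = n_extra >= k
        if not m.any():
            continue
        frac = rng.uniform(0.1, 0.9, int(m.sum()))
        zk = z1[m] * (1.0 - frac) ** k
        xs.append(px[m]); ys.append(py[m]); zs.append(np.maximum(zk, 0.0))
        rns.append(np.full(int(m.sum()), k + 1))
        grounds.append(np.zeros(int(m.sum()), dtype=bool))
    x = np.concatenate(xs); y = np.concatenate(ys); z = np.concatenate(zs)
    rn = np.concatenate(rns)
    total = 1 + n_extra
    nr_first = total
    nrs = [nr_first]
    for k in range(1, 4):
        nrs.append(total[n_extra >= k])
    nr = np.concatenate(nrs)
    ground = np.concatenate(grounds)
    return PointCloud(x, y, z, rn, nr, ground)


# ---------------------------------------------------------------------------
# hyperspectral cube
# ---------------------------------------------------------------------------


def make_spectral_classes(species: list[str], n_bands: int, target_jm: float,
                          noise_sd: float, seed: int = 0):
    """Gaussian class models with an exact prescribed pairwise JM distance.

    Class means sit at the vertices of a regular simplex (equal pairwise
    distance) on top of a smooth positive base spectrum, with isotropic
    covariance.  For equal covariances the Bhattacharyya distance reduces to
    ``B = d^2 / (8 sigma^2)``, so the simplex edge ``d`` is solved from the
    JM target ``JM = 2 (1 - exp(-B))``.
    """
    if not 0 < target_jm < 2:
        raise ValueError("target_jm must be in (0, 2)")
    rng = np.random.default_rng(seed)
    k = len(species)
    if k > n_bands:
        raise ValueError("need n_bands >= number of classes")
    b = -np.log(1.0 - target_jm / 2.0)
    d = noise_sd * np.sqrt(8.0 * b)
    base = 0.5 + 0.3 * np.sin(np.linspace(0, np.pi, n_bands)) \
        + 0.05 * rng.random(n_bands)
    means = {}
    scale = d / np.sqrt(2.0)
    for i, s in enumerate(species):
        e = np.zeros(n_bands)
        e[i] = scale
        means[s] = base + e
    cov = noise_sd ** 2 * np.eye(n_bands)
    return means, cov


def simulate_hypercube(forest: pd.DataFrame, scenario: ForestScenario
                       ) -> tuple[HyperCube, pd.DataFrame]:
    """Reflectance cube over the stand plus the labelled pixel table.

    Per-pixel spectra are drawn from the owning species' Gaussian;
    crown-edge pixels are darkened by the shading factor (exercising sunlit
    extraction); open ground gets a flat soil spectrum.  The pixel table
    lists (row, col, tree id, species) for every crown pixel.
    """
    rng = np.random.default_rng(scenario.seed + 2)
    ext = scenario.extent_m
    res = scenario.cube_resolution
    n = int(np.round(ext / res))
    species = list(scenario.species_mix)
    means, cov = make_spectral_classes(species, scenario.n_bands,
                                       scenario.target_jm,
                                       scenario.spectral_noise_sd,
                                       scenario.seed)
    sd = np.sqrt(np.diag(cov))
    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    cx = (cols.ravel() + 0.5) * res
    cy = ext - (rows.ravel() + 0.5) * res
    over = forest[~forest["understorey"]] if "understorey" in forest else forest
    surf, owner = _crown_surface(over.reset_index(drop=True), cx, cy,
                                 scenario.crown_base_frac)
    soil = 0.25 + 0.02 * np.sin(np.linspace(0, 3, scenario.n_bands))
    cube_vals = np.empty((scenario.n_bands, n, n))
    recs = []
    over_reset = over.reset_index(drop=True)
    for p in range(cx.size):
        r, c = divmod(p, n)
        if owner[p] < 0:
            spec = soil + rng.normal(0, scenario.spectral_noise_sd, scenario.n_bands)
        else:
            t = over_reset.iloc[owner[p]]
            spec = means[t["species"]] + rng.normal(0, 1, scenario.n_bands) * sd
            d = np.hypot(cx[p] - t["x"], cy[p] - t["y"])
            if d / t["crown_radius_m"] > scenario.shaded_edge_frac:
                spec = spec * scenario.shading_factor
            recs.append({"row": r, "col": c, "tree_id": int(t["id"]),
                         "species": t["species"]})
        cube_vals[:, r, c] = np.clip(spec, 1e-6, None)
    cube = HyperCube(0.0, ext, res, cube_vals,
                     np.linspace(400, 990, scenario.n_bands))
    return cube, pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# field inventory
# ---------------------------------------------------------------------------


def simulate_inventory(forest: pd.DataFrame, scenario: ForestScenario,
                       n_plots: int = 10, radius_m: float | None = 15.0,
                       basal_area_factor: float | None = None,
                       seed: int | None = None) -> list[Plot]:
    """Sample field plots and attach measured (noisy) tree records.

    Fixed-radius plots include every stem inside the circle; angle-count
    plots apply the Bitterlich rule at the given basal-area factor.  DBH and
    height carry multiplicative measurement error (1.5% and 5% by default).
    """
    from .matching_eval import FieldTree

    rng = np.random.default_rng(scenario.seed + 3 if seed is None else seed)
    ext = scenario.extent_m
    margin = radius_m if radius_m is not None else 0.0
    margin = min(margin, ext / 2 * 0.99)
    plots: list[Plot] = []
    for pid in range(1, n_plots + 1):
        cx = rng.uniform(margin, ext - margin)
        cy = rng.uniform(margin, ext - margin)
        plot = Plot(id=pid, x=cx, y=cy, radius_m=radius_m,
                    basal_area_factor=basal_area_factor)
        for _, t in forest.iterrows():
            dist = float(np.hypot(t["x"] - cx, t["y"] - cy))
            if radius_m is not None:
                included = dist <= radius_m
            else:
                included = bitterlich_included(t["dbh_cm"], dist, basal_area_factor)
            if not included:
                continue
            dbh_meas = t["dbh_cm"] * np.exp(rng.normal(0, scenario.dbh_measure_cv))
            h_meas = t["height_m"] * np.exp(rng.normal(0, scenario.height_measure_cv))
            plot.trees.append(FieldTree(
                id=int(t["id"]), x=float(t["x"]), y=float(t["y"]),
                species=t["species"], dbh_cm=float(dbh_meas),
                height_m=float(h_meas), plot_id=pid,
                agb_kg=float(t["agb_kg"]), carbon_kg=float(t["carbon_kg"])))
        plots.append(plot)
    return plots
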