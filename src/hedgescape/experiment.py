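"""Sobol experimental design and replicated simulation orchestration.

The design space is the set of model parameters that vary over a range:
landscape composition/configuration (crop and hedge proportions,
aggregation), movement (diffusions, hedge-to-field migration) and
demography (growth, predation).  Samples come from a scrambled Sobol
low-discrepancy sequence arranged in the radial A/B/AB_i blocks required
by the Saltelli (first-order) and Jansen (total) index estimators, so a
design with k factors and base sample N counts N*(k+2) distinct
configurations.  Each configuration is simulated on several landscape
replicates (replicate seeds are shared across configurations, i.e. common
random numbers).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import dynamics as dyn
from .landscape import (
    GRFConfig,
    Tessellation,
    allocate,
    build_tessellation_fixture,
    compute_metrics,
)
from .mesh import build_mesh

__all__ = [
    "Factor",
    "FACTORS",
    "DesignSpec",
    "DesignMatrix",
    "build_design",
    "run_design",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class Factor:
    """A design factor: sampling range plus how it enters the model.

    ``target`` is ``(section, name)`` with section ``landscape`` or
    ``species``.  ``invert`` marks parameters sampled on the lifespan
    scale (days) and applied as a mortality rate 1/x.
    """

    name: str
    low: float
    high: float
    target: tuple[str, str]
    invert: bool = False


#: Registry of supported factors (sampling ranges of the varied parameters).
FACTORS: dict[str, Factor] = {
    f.name: f
    for f in [
        Factor("phi", 5.55 / 100, 5.55, ("landscape", "phi")),
        Factor("p_crop", 0.0, 1.0, ("landscape", "p_crop")),
        Factor("p_hedge", 0.0, 1.0, ("landscape", "p_hedge")),
        Factor("d2v", 0.000625, 0.012, ("species", "d2v")),
        Factor("rho12", 0.0, 0.05, ("species", "rho12")),
        Factor("d2u", 0.000625, 0.012, ("species", "d2u")),
        Factor("beta", 0.01, 0.10, ("species", "beta")),
        Factor("r_u", 0.010, 0.020, ("species", "r_u")),
        Factor("r_v", 0.010, 0.020, ("species", "r_v")),
        Factor("lifespan_v", 20.0, 66.0, ("species", "m_v"), invert=True),
        Factor("lifespan_u", 20.0, 66.0, ("species", "m_u"), invert=True),
    ]
}

#: Default varied set: the eight parameters whose effects the analysis
#: layer reports; with the radial block layout this reproduces the
#: 11,500-configuration arithmetic (N = 1150 blocks of k + 2 = 10).
DEFAULT_FACTORS = (
    "phi",
    "p_crop",
    "p_hedge",
    "d2v",
    "rho12",
    "d2u",
    "beta",
    "r_u",
)


@dataclass
class DesignSpec:
    """Specification of a replicated Sobol design."""

    factors: tuple[str, ...] = DEFAULT_FACTORS
    n_configs: int = 11500
    n_landscape_replicates: int = 15
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = [f for f in self.factors if f not in FACTORS]
        if unknown:
            raise ValueError(
                f"unknown factors {unknown}; available: {sorted(FACTORS)}"
            )
        k = len(self.factors)
        if self.n_configs % (k + 2):
            raise ValueError(
                f"n_configs={self.n_configs} is incompatible with the "
                f"Saltelli block structure: with k={k} factors the design "
                f"holds N*(k+2) configurations (blocks A, B and one AB "
                f"block per factor), so n_configs must be a multiple of "
                f"{k + 2}"
            )
        if self.n_landscape_replicates < 1:
            raise ValueError("need at least one landscape replicate")

    @property
    def base_sample_size(self) -> int:
        return self.n_configs // (len(self.factors) + 2)


@dataclass
class DesignMatrix:
    """Design rows plus the block bookkeeping the estimators need."""

    spec: DesignSpec
    configs: pd.DataFrame  # one row per configuration
    rows: pd.DataFrame  # configurations x replicates, with seeds

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def build_design(spec: DesignSpec) -> DesignMatrix:
    """Sample the Saltelli radial blocks and attach replicate seeds.

    Block layout (base sample N, k factors): configurations
    ``0..N-1`` are the A block, ``N..2N-1`` the B block, then one AB_i
    block per factor in which column i of A is replaced by column i of B.
    The ``block`` and ``base_index`` columns recover this structure.
    """
    k = len(spec.factors)
    n = spec.base_sample_size
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=spec.seed)
    with warnings.catch_warnings():
        # the radial estimators do not need a power-of-two base sample
        warnings.simplefilter("ignore", UserWarning)
        base = sampler.random(n)
    a, b = base[:, :k], base[:, k:]

    blocks = [("A", a), ("B", b)]
    for i, name in enumerate(spec.factors):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append((f"AB_{name}", ab))

    frames = []
    for label, mat in blocks:
        df = pd.DataFrame(mat, columns=list(spec.factors))
        df.insert(0, "block", label)
        df.insert(1, "base_index", np.arange(n))
        frames.append(df)
    configs = pd.concat(frames, ignore_index=True)
    configs.index.name = "config_id"
    # scale the unit hypercube to the factor ranges
    for name in spec.factors:
        f = FACTORS[name]
        configs[name] = f.low + configs[name] * (f.high - f.low)
    configs = configs.reset_index()

    # replicate seeds: common random numbers across configurations
    ss = np.random.SeedSequence(spec.seed)
    rep_states = ss.generate_state(2 * spec.n_landscape_replicates) % (2**31)
    reps = pd.DataFrame(
        {
            "replicate_id": np.arange(spec.n_landscape_replicates),
            "landscape_seed": rep_states[::2],
            "dynamics_seed": rep_states[1::2],
        }
    )
    rows = configs.merge(reps, how="cross")
    return DesignMatrix(spec=spec, configs=configs, rows=rows)


def _apply_row(row: pd.Series, spec: DesignSpec, grf: GRFConfig,
               species: dyn.SpeciesParams) -> tuple[GRFConfig, dyn.SpeciesParams]:
    grf_kw: dict[str, float] = {}
    sp_kw: dict[str, float] = {}
    for name in spec.factors:
        f = FACTORS[name]
        value = float(row[name])
        if f.invert:
            value = 1.0 / value
        (grf_kw if f.target[0] == "landscape" else sp_kw)[f.target[1]] = value
    return replace(grf, **grf_kw), replace(species, **sp_kw)


def _run_key(row: pd.Series, spec: DesignSpec) -> str:
    payload = json.dumps(
        {n: float(row[n]) for n in spec.factors}
        | {
            "rep": int(row["replicate_id"]),
            "ls": int(row["landscape_seed"]),
            "ds": int(row["dynamics_seed"]),
        },
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def run_design(
    design: DesignMatrix,
    tess: Tessellation,
    *,
    species: dyn.SpeciesParams | None = None,
    grf: GRFConfig | None = None,
    pesticide: dyn.PesticideConfig | None = None,
    inoculation: dyn.InoculationConfig | None = None,
    resolution: float = 0.2,
    dt_internal: float = 0.2,
    collect_fields: bool = False,
    resume_dir: str | Path | None = None,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Execute every design row on the given tessellation.

    Returns the run-level results table and, when ``collect_fields`` is
    set, a per-field long table for the local (patch-scale) analysis.
    Individual run failures are recorded in the ``failed`` column rather
    than aborting the design.  With ``resume_dir`` each finished run is
    checkpointed to a JSON file keyed by its parameter hash and picked up
    again on a rerun.
    """
    species = species or dyn.SpeciesParams()
    grf = grf or GRFConfig()
    pesticide = pesticide or dyn.PesticideConfig()
    inoculation = inoculation or dyn.InoculationConfig()
    spec = design.spec
    resume = Path(resume_dir) if resume_dir is not None else None
    if resume is not None:
        resume.mkdir(parents=True, exist_ok=True)

    out_rows: list[dict] = []
    field_rows: list[dict] = []
    iterator = design.rows.iterrows()
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, total=len(design.rows))

    for _, row in iterator:
        key = _run_key(row, spec)
        cache = resume / f"run_{key}.json" if resume is not None else None
        if cache is not None and cache.exists():
            with open(cache) as fh:
                cached = json.load(fh)
            out_rows.append(cached["run"])
            field_rows.extend(cached.get("fields", []))
            continue
        base = {
            "config_id": int(row["config_id"]),
            "replicate_id": int(row["replicate_id"]),
            "block": row["block"],
            "base_index": int(row["base_index"]),
            **{n: float(row[n]) for n in spec.factors},
        }
        try:
            run_rec, frecs = _run_one(
                row, spec, tess, grf, species, pesticide, inoculation,
                resolution, dt_internal, collect_fields,
            )
        except Exception as err:  # noqa: BLE001 - record, don't abort
            out_rows.append({**base, "failed": str(err)})
            continue
        run_rec = {**base, "failed": "", **run_rec}
        frecs = [{**base, **fr} for fr in frecs]
        out_rows.append(run_rec)
        field_rows.extend(frecs)
        if cache is not None:
            with open(cache, "w") as fh:
                json.dump({"run": run_rec, "fields": frecs}, fh)

    results = pd.DataFrame(out_rows)
    fields = pd.DataFrame(field_rows) if collect_fields else None
    return results, fields


def _run_one(row, spec, tess, grf, species, pesticide, inoculation,
             resolution, dt_internal, collect_fields):
    grf_cfg, sp = _apply_row(row, spec, grf, species)
    grf_cfg = replace(grf_cfg, seed=int(row["landscape_seed"]))
    alloc = allocate(tess, grf_cfg)
    mesh = build_mesh(tess, alloc, resolution)
    summary = dyn.run_simulation(
        tess,
        alloc,
        sp,
        pesticide,
        inoculation,
        seed=int(row["dynamics_seed"]),
        mesh=mesh,
        dt_internal=dt_internal,
    )
    metrics = compute_metrics(tess, alloc)
    run_rec = {
        "mean_pest": summary.mean_pest,
        "mean_predator": summary.mean_predator,
        "n_applications": summary.n_applications_total,
        "presence": int(summary.presence_any),
        "p_crop_real": metrics.p_crop_realized,
        "p_hedge_real": metrics.p_hedge_realized,
        "crop_aggregation": metrics.crop_aggregation,
        "crop_hedge_interface": metrics.crop_hedge_interface,
    }
    frecs: list[dict] = []
    if collect_fields:
        n_apps = summary.n_applications
        adj_trt = np.zeros(tess.n_polygons)
        for i in range(tess.n_polygons):
            adj_trt[i] = sum(
                n_apps[j]
                for j in tess.neighbours(i)
                if alloc.crop_label[j]
            )
        for i in np.flatnonzero(alloc.crop_label):
            frecs.append(
                {
                    "polygon": int(i),
                    "area": float(metrics.area[i]),
                    "perimeter": float(metrics.perimeter[i]),
                    "adj_crop": int(metrics.n_adjacent_crop[i]),
                    "adj_hedges": int(metrics.n_adjacent_hedges[i]),
                    "adj_treatments": float(adj_trt[i]),
                    "n_applications": int(n_apps[i]),
                    "presence": int(n_apps[i] > 0),
                }
            )
    return run_rec, frecs


def aggregate_replicates(results: pd.DataFrame,
                         outputs: tuple[str, ...] = (
                             "mean_pest",
                             "mean_predator",
                             "n_applications",
                             "presence",
                         )) -> pd.DataFrame:
    """Per-configuration mean and standard deviation over replicates.

    Output columns are ``<channel>_mean`` and ``<channel>_sd``; the sd
    columns are NaN when a configuration has a single replicate (flagged
    in the ``sd_available`` column).
    """
    ok = (
        results[results["failed"] == ""]
        if "failed" in results.columns
        else results
    )
    keys = ["config_id", "block", "base_index"]
    grouped = ok.groupby(keys, sort=True)
    agg = grouped[list(outputs)].agg(["mean", "std"])
    agg.columns = [f"{c}_{s.replace('std', 'sd')}" for c, s in agg.columns]
    agg["n_replicates"] = grouped.size()
    agg["sd_available"] = agg["n_replicates"] >= 2
    factor_cols = [
        c for c in ok.columns
        if c in FACTORS
    ]
    agg = agg.join(grouped[factor_cols].first())
    return agg.reset_index()


def default_tessellation(
    extent: float = 5.55, n_polygons: int = 188, seed: int = 0
) -> Tessellation:
    """The fixed geometric support used across a design's runs."""
    return build_tessellation_fixture(extent, n_polygons, seed)
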