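"""Configuration, reporting and reproducibility plumbing.

Ties the lattice, path census, assembly engine and GA together behind a
single serialisable run configuration, and renders the standard summary
tables: per-move-set census/yield tables, optimised-versus-uniform yield
comparisons, and dominant-path frequency reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import KineticParams, RNAVariant, run_assembly
from .landscape import (
    DEFAULT_BANDS,
    GAConfig,
    knockout,
    nucleation_only,
    nucleation_site,
)
from .lattice import DEFAULT_FRAME, CapsidLattice, FrameConfig, MoveSet, build_lattice
from .paths import PathCensus, classify_paths, count_paths

#: move sets with at least this many moves are census-skipped in reports
CENSUS_SKIP_SIZE = 8


@dataclass
class RunConfig:
    """A fully serialisable description of one analysis run."""

    move_set: str = "2345"
    frame: FrameConfig = field(default_factory=FrameConfig)
    kinetics: KineticParams = field(default_factory=KineticParams)
    ga: GAConfig = field(default_factory=GAConfig)
    rna_profile: str = "uniform:-9"  # uniform:<dg> | csv:<path>
    n_rna: int = 2000
    seed: int = 1
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame"] = self.frame.to_dict()
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "frame" in d:
            fr = d["frame"]
            fr["weights"] = tuple(fr.get("weights", DEFAULT_FRAME.weights))
            d["frame"] = FrameConfig(**fr)
        if "kinetics" in d:
            d["kinetics"] = KineticParams(**d["kinetics"])
        if "ga" in d:
            ga = d["ga"]
            ga["bounds"] = tuple(ga.get("bounds", (-12.0, -4.0)))
            d["ga"] = GAConfig(**ga)
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def resolve_variant(self) -> RNAVariant:
        kind, _, arg = self.rna_profile.partition(":")
        if kind == "uniform":
            return RNAVariant.uniform(float(arg))
        if kind == "csv":
            table = pd.read_csv(arg)
            return RNAVariant(table["dg_ps"].to_numpy())
        raise ValueError(f"unknown RNA profile {self.rna_profile!r}")


def variant_to_csv(variant: RNAVariant, path) -> None:
    pd.DataFrame({"index": np.arange(30), "dg_ps": variant.dg_ps}).to_csv(
        path, index=False
    )


def _round_ncap(n_cap: int) -> str:
    """Published rounding: nearest 10, negligible-but-nonzero shown as <10."""
    if 0 < n_cap < 10:
        return "<10"
    return str(int(round(n_cap / 10.0) * 10))


def make_table1(
    move_sets: list[MoveSet],
    config: RunConfig,
    lattice: CapsidLattice | None = None,
    census_limit: int | None = None,
) -> pd.DataFrame:
    """Census and uniform-affinity assembly summary per move set.

    For each move set: number of moves, exhaustive path count (skipped for
    8/9-move sets unless a node budget is given), capsids assembled from a
    uniform dG_ps = -9 ensemble (raw and rounded to the nearest 10), the
    runtime and the seed.  An empty move-set list yields a header-only
    table.
    """
    lattice = lattice if lattice is not None else build_lattice(config.frame)
    rows = []
    for ms in move_sets:
        t0 = time.perf_counter()
        if ms.size >= CENSUS_SKIP_SIZE and census_limit is None:
            n_path: int | str = "skipped"
            convention = "-"
        else:
            census = count_paths(lattice, ms, limit=census_limit)
            n_path = census.n_path if census.complete else f">={census.n_path}"
            convention = census.counting_convention
        res = run_assembly(
            RNAVariant.uniform(-9.0),
            config.kinetics,
            ms,
            seed=config.seed,
            n_rna=config.n_rna,
            lattice=lattice,
        )
        rows.append(
            {
                "N": ms.size,
                "move_set": "".join(str(m) for m in ms),
                "n_path": n_path,
                "counting_convention": convention,
                "n_cap_raw": res.n_cap,
                "n_cap": _round_ncap(res.n_cap),
                "yield_pct": res.yield_pct,
                "runtime_s": round(time.perf_counter() - t0, 2),
                "seed": config.seed,
                "config_hash": config.config_hash(),
            }
        )
    columns = [
        "N", "move_set", "n_path", "counting_convention", "n_cap_raw",
        "n_cap", "yield_pct", "runtime_s", "seed", "config_hash",
    ]
    return pd.DataFrame(rows, columns=columns)


def make_table2(
    move_set: MoveSet,
    optimal: RNAVariant,
    config: RunConfig,
    lattice: CapsidLattice | None = None,
    n_seeds: int = 5,
    uniform_levels: tuple[float, ...] = (-4.0, -8.0, -10.0),
) -> pd.DataFrame:
    """Optimised-versus-uniform yield comparison for one move set.

    Mean assembly yield over `n_seeds` seed-distinct stochastic runs for
    uniform profiles, the optimised variant, its nucleation-site knockout
    and the nucleation-site-only profile (six columns per move set).
    """
    lattice = lattice if lattice is not None else build_lattice(config.frame)
    profiles: dict[str, RNAVariant] = {
        str(dg): RNAVariant.uniform(dg) for dg in uniform_levels
    }
    profiles["optimal"] = optimal
    site = nucleation_site(optimal, DEFAULT_BANDS)
    if site is not None:
        profiles["knockout"] = knockout(optimal)
        profiles["nuc_only"] = nucleation_only(optimal)
    seeds = [int(s) for s in np.random.SeedSequence(config.seed).generate_state(n_seeds) >> 1]
    row: dict[str, object] = {
        "move_set": "".join(str(m) for m in move_set),
        "n_rna": config.n_rna,
        "n_seeds": n_seeds,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    for name, variant in profiles.items():
        yields = [
            run_assembly(
                variant, config.kinetics, move_set, seed=s,
                n_rna=config.n_rna, lattice=lattice,
            ).yield_pct
            for s in seeds
        ]
        row[f"yield_{name}"] = float(np.mean(yields))
    return pd.DataFrame([row])


def report_paths(results, census: PathCensus | None = None, top: int = 5) -> pd.DataFrame:
    """Dominant path-type frequencies across one or more assembly runs.

    Rows: canonical label, count, relative frequency; the table's attrs
    carry the shared-prefix annotation of the top path types.
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    paths = [p for res in results for p in res.paths]
    cls = classify_paths(paths, census=census, top=2)
    table = cls.table.head(top).copy()
    table.attrs["n_paths"] = cls.n_paths
    table.attrs["top_shared_prefix"] = cls.top_shared_prefix
    table.attrs["top_shared_prefix_len"] = cls.top_shared_prefix_len
    table.attrs["all_in_census"] = cls.all_in_census
    return table


def write_report(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Write a CSV report; the config hash and seed are embedded columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = df.copy()
    if config is not None and "config_hash" not in df.columns:
        df["config_hash"] = config.config_hash()
        df["seed"] = config.seed
    df.to_csv(path, index=False)
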