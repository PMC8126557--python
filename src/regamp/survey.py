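"""Census pipeline: enumerate -> coalescence -> perturb -> spectral -> fixation.

Runs the amplifier-constructor survey over all connected nonisomorphic
k-regular graphs of a given order and collects one record per graph: the
remeeting-time statistics, the spectral gap and von Neumann entropy, the
best effective population size reachable by edge removal at the
max-remeeting vertex, the constructor verdict, and (optionally, for
constructors of modest order) the transient-amplification bound r_max.

Graphs are processed in the deterministic canonical stream order, so
re-running a census reproduces the output byte for byte.  When an output
directory is given, records are appended to ``census.csv`` as they are
computed and an interrupted run resumes from the rows already present.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import classify as _classify
from .coalescence import coalescence_times, perturb_search, remeeting_statistics
from .fixation import find_r_max
from .graphgen import enumerate_regular, write_graph6
from .spectral import FamilySpectral, SpectralSummary, default_grid, spectral_distance

__all__ = ["RunConfig", "CensusResult", "run_census", "export_figure_data"]

CENSUS_COLUMNS = [
    "graph6",
    "n",
    "k",
    "max_tau",
    "var_tau",
    "lambda2",
    "entropy",
    "n_eff_best",
    "is_constructor",
    "removed_edges",
    "r_max",
]


@dataclass
class RunConfig:
    """Serializable description of one census run."""

    order: int
    degree: int
    n_remove: int = 1
    removal_mode: str = "simultaneous"
    rmax_for_constructors: bool = False
    rmax_cap: int = 14
    rmax_points: int = 13
    rmax_window: float = 0.01
    out_dir: str | None = None
    backend: str | None = None
    seed: int = 0

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class CensusResult:
    records: pd.DataFrame
    summary: dict
    config: RunConfig

    def constructors(self) -> pd.DataFrame:
        return self.records[self.records["is_constructor"]]

    def classifier_report(self):
        return _classify.fit_and_score(self.records)


def _format_edges(edges) -> str:
    return ";".join(f"{u}-{v}" for u, v in edges) if edges else ""


def survey_graph(g: nx.Graph, config: RunConfig) -> dict:
    """Run the full per-graph pipeline and return one census record."""
    from .graphgen import canonical_graph6

    n = g.number_of_nodes()
    k = g.degree(next(iter(g.nodes())))
    outcome = perturb_search(g, n_remove=config.n_remove, mode=config.removal_mode)
    mean_tau, var_tau, max_tau = remeeting_statistics(outcome.summary)
    spec = SpectralSummary.from_graph(g)

    r_max = np.nan
    best = outcome.best_removal
    if (
        config.rmax_for_constructors
        and outcome.is_constructor
        and n <= config.rmax_cap
        and best is not None
    ):
        h = g.copy()
        h.remove_edges_from(best.edges)
        curve = find_r_max(
            h, n_points=config.rmax_points, window=config.rmax_window, cap=config.rmax_cap
        )
        if curve.r_max is not None:
            r_max = curve.r_max

    return {
        "graph6": canonical_graph6(g),
        "n": n,
        "k": k,
        "max_tau": max_tau,
        "var_tau": var_tau,
        "lambda2": spec.spectral_gap,
        "entropy": spec.entropy,
        "n_eff_best": outcome.best_n_eff if outcome.best_n_eff is not None else np.nan,
        "is_constructor": outcome.is_constructor,
        "removed_edges": _format_edges(best.edges) if best is not None else "",
        "r_max": r_max,
    }


def run_census(config: RunConfig | None = None, **kwargs) -> CensusResult:
    """Survey every connected nonisomorphic k-regular graph of one order.

    Either pass a :class:`RunConfig` or its fields as keyword arguments
    (``run_census(order=12, degree=3)``).
    """
    if config is None:
        config = RunConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a RunConfig or keyword arguments, not both")

    out_dir = config.out_dir
    done: dict[str, dict] = {}
    csv_path = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        csv_path = os.path.join(out_dir, "census.csv")
        if os.path.exists(csv_path):
            prior = pd.read_csv(
                csv_path,
                keep_default_na=False,
                na_values=[""],
                float_precision="round_trip",  # default parser drifts by 1 ulp
            )
            for rec in prior.to_dict("records"):
                done[rec["graph6"]] = rec

    rows = []
    for g in enumerate_regular(config.order, config.degree, backend=config.backend):
        g6 = nx.to_graph6_bytes(g, header=False).decode().strip()
        if g6 in done:
            rows.append(done[g6])
            continue
        rec = survey_graph(g, config)
        rows.append(rec)
        if csv_path is not None:
            header = not os.path.exists(csv_path)
            pd.DataFrame([rec], columns=CENSUS_COLUMNS).to_csv(
                csv_path, mode="a", header=header, index=False, float_format="%.17g"
            )

    records = pd.DataFrame(rows, columns=CENSUS_COLUMNS)
    records["is_constructor"] = records["is_constructor"].astype(bool)
    n_constructors = int(records["is_constructor"].sum())
    summary = {
        "order": config.order,
        "degree": config.degree,
        "n_graphs": len(records),
        "n_constructors": n_constructors,
        "constructor_fraction": n_constructors / len(records) if len(records) else 0.0,
    }
    result = CensusResult(records=records, summary=summary, config=config)

    if out_dir is not None:
        # rewrite the census in canonical order so resumed runs converge
        records.to_csv(csv_path, index=False, float_format="%.17g")
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        cons = records[records["is_constructor"]]["graph6"].tolist()
        with open(os.path.join(out_dir, "constructors.g6"), "w") as fh:
            for line in cons:
                fh.write(line + "\n")
        config.to_file(os.path.join(out_dir, "config.json"))
    return result


def export_figure_data(result: CensusResult, out_dir: str) -> dict[str, str]:
    """Write the scatter and density tables behind the survey figures as CSV.

    Returns a mapping from table name to file path.  The constructor-family
    density/distance export is skipped (with a warning) when the slice has
    no constructors.
    """
    os.makedirs(out_dir, exist_ok=True)
    rec = result.records
    written: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(out_dir, name)
        df.to_csv(path, index=False)
        written[name.removesuffix(".csv")] = path

    ratio = rec["n_eff_best"] / rec["n"]
    _write(
        "remeeting_scatter.csv",
        pd.DataFrame(
            {
                "graph6": rec["graph6"],
                "var_tau": rec["var_tau"],
                "max_tau": rec["max_tau"],
                "n_eff_ratio": ratio,
                "is_constructor": rec["is_constructor"],
            }
        ),
    )
    _write(
        "gap_scatter.csv",
        pd.DataFrame(
            {
                "graph6": rec["graph6"],
                "lambda2": rec["lambda2"],
                "max_tau": rec["max_tau"],
                "n_eff_ratio": ratio,
                "is_constructor": rec["is_constructor"],
            }
        ),
    )
    _write(
        "entropy_scatter.csv",
        pd.DataFrame(
            {
                "graph6": rec["graph6"],
                "entropy": rec["entropy"],
                "n_eff_ratio": ratio,
                "is_constructor": rec["is_constructor"],
            }
        ),
    )
    if rec["r_max"].notna().any():
        sub = rec[rec["r_max"].notna()]
        _write(
            "rmax_scatter.csv",
            pd.DataFrame(
                {
                    "graph6": sub["graph6"],
                    "n_eff_ratio": sub["n_eff_best"] / sub["n"],
                    "r_max": sub["r_max"],
                }
            ),
        )

    grid = default_grid()
    spectra = {
        g6: SpectralSummary.from_graph(nx.from_graph6_bytes(g6.encode()), grid)
        for g6 in rec["graph6"]
    }
    all_dens = np.array([s.density for s in spectra.values()])
    fam_all = FamilySpectral(grid=grid, member_densities=all_dens)
    cons_mask = rec["is_constructor"].to_numpy()
    density_table = {"x": grid, "phi_all": fam_all.family_density}
    distances = {}
    rest = FamilySpectral(grid=grid, member_densities=all_dens[~cons_mask])
    density_table["phi_rest"] = rest.family_density
    distances["rest_vs_all"] = spectral_distance(rest, fam_all)
    if cons_mask.any():
        cons = FamilySpectral(grid=grid, member_densities=all_dens[cons_mask])
        density_table["phi_constructors"] = cons.family_density
        distances["constructors_vs_all"] = spectral_distance(cons, fam_all)
        distances["constructors_vs_rest"] = spectral_distance(cons, rest)
    else:
        warnings.warn(
            "census slice has no amplifier constructors; "
            "constructor family density export skipped"
        )
    _write("family_density.csv", pd.DataFrame(density_table))
    path = os.path.join(out_dir, "family_distance.json")
    with open(path, "w") as fh:
        json.dump(distances, fh, indent=2, sort_keys=True)
    written["family_distance"] = path
    return written
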