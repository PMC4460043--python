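"""End-to-end orchestration: classify -> network -> date -> route test.

`run_full_analysis` is a pure function of (inputs, config, seed): it reads
a haplotype table, assigns haplogroups, builds and resolves one median
network per clade rooted on the clade's ancestral motif, dates each clade
with rho/sigma, computes geographic ranges and centers, runs the
longitude-gradient concordance test for each configured route table, and
writes plain-text TSV/JSON outputs plus a run manifest recording
versions, seed and the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_haplotype, is_NxR, load_haplogroup_tree
from .dating import Calibration, date_clade
from .errors import ContractViolation, MtrouteError, ValidationError
from .network import build_mj_network, mp_prune, resolve_reticulations
from .phylogeo import (
    Anchor,
    RouteModel,
    RouteObservation,
    compute_range,
    concordance_test,
    ranges_to_geojson,
    read_route_table,
)
from .seqio import read_haplotype_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    input_table: Path
    output_dir: Path
    seed: int = 0
    haplogroup_tree: Path | None = None  # packaged fixture when None
    epsilon: int = 0
    calibration_mode: str = "linear"
    calibration_rate: float = 3624.0
    calibration_coefficients: tuple[float, ...] = ()
    anchors: Path | None = None  # packaged anchors when None
    routes: dict[str, Path] = dataclass_field(default_factory=dict)
    min_clade_size: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent

        def resolve(p):
            return (base / p).resolve() if p else None

        cal = raw.get("calibration", {}) or {}
        cfg = cls(
            input_table=resolve(raw.get("input_table")),
            output_dir=(base / raw.get("output_dir", "out")).resolve(),
            seed=int(raw.get("seed", 0)),
            haplogroup_tree=resolve(raw.get("haplogroup_tree")),
            epsilon=int(raw.get("epsilon", 0)),
            calibration_mode=cal.get("mode", "linear"),
            calibration_rate=float(cal.get("rate", 3624.0)),
            calibration_coefficients=tuple(cal.get("coefficients", ())),
            anchors=resolve(raw.get("anchors")),
            routes={name: resolve(p) for name, p in (raw.get("routes") or {}).items()},
            min_clade_size=int(raw.get("min_clade_size", 2)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.input_table is None or not Path(self.input_table).exists():
            raise ValidationError(f"input table {self.input_table} does not exist")
        for name, p in self.routes.items():
            if not Path(p).exists():
                raise ValidationError(f"route table {name!r}: {p} does not exist")
        for label, p in (("haplogroup_tree", self.haplogroup_tree), ("anchors", self.anchors)):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{label} path {p} does not exist")

    def calibration(self) -> Calibration:
        return Calibration(
            mode=self.calibration_mode,
            rate=self.calibration_rate,
            coefficients=self.calibration_coefficients,
        )


def load_anchor_model(path: str | Path | None = None) -> RouteModel:
    """Anchor model from YAML (packaged Djibouti/Darwin anchors by default)."""
    if path is None:
        from importlib import resources

        source = resources.files("mtroute.data") / "anchors.yaml"
        with resources.as_file(source) as p:
            raw = yaml.safe_load(Path(p).read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    from .seqio import parse_coordinates

    def to_anchor(rec: dict) -> Anchor:
        lon = parse_coordinates(rec["coordinates"]).longitude
        lo, hi = rec["ci95_ky"]
        return Anchor(rec["name"], lon, float(rec["age_ky"]), (float(lo), float(hi)))

    return RouteModel(anchor_west=to_anchor(raw["west"]), anchor_east=to_anchor(raw["east"]))


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write the summary tables; returns the manifest."""
    cfg.validate()
    t_start = time.perf_counter()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}
    manifest: dict = {
        "tool": "mtroute",
        "version": __version__,
        "seed": cfg.seed,
        "numpy": np.__version__,
        "outputs": [],
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timers[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise MtrouteError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s done in %.3fs", name, timers[name])

        return _Timer()

    with stage("read"):
        haplotypes = read_haplotype_table(cfg.input_table)
        if not haplotypes:
            raise ValidationError(f"input table {cfg.input_table} holds no samples")
        tree_fixture = load_haplogroup_tree(cfg.haplogroup_tree)

    with stage("classify"):
        calls = []
        for h in haplotypes:
            res = classify_haplotype(h, tree_fixture)
            calls.append(
                {
                    "sample_id": h.sample_id,
                    "haplogroup": res.haplogroup,
                    "score": res.score,
                    "mismatches": res.mismatches,
                    "ambiguous": int(res.ambiguous),
                    "n_xr": int(is_NxR(res, tree_fixture))
                    if res.haplogroup in tree_fixture.nodes
                    else 0,
                }
            )
        calls_df = pd.DataFrame(calls).sort_values("sample_id")
        calls_path = outdir / "calls.tsv"
        calls_df.to_csv(calls_path, sep="\t", index=False)
        manifest["outputs"].append(str(calls_path))

    with stage("date"):
        by_group: dict[str, list] = {}
        call_of = {c["sample_id"]: c["haplogroup"] for c in calls}
        for h in haplotypes:
            by_group.setdefault(call_of[h.sample_id], []).append(h)
        cal = cfg.calibration()
        age_rows = []
        estimates = {}
        for name in sorted(by_group):
            members = by_group[name]
            if len(members) < cfg.min_clade_size:
                logger.info("skipping %s: only %d member(s)", name, len(members))
                continue
            motif = tree_fixture.cumulative_motif(name)
            net = build_mj_network(members, epsilon=cfg.epsilon, outgroup=motif)
            net = mp_prune(net)
            rtree = resolve_reticulations(net, outgroup=motif)
            est = date_clade(rtree, cal, clade=name)
            estimates[name] = est
            age_rows.append(
                {
                    "haplogroup": name,
                    "n": est.n_tips,
                    "rho": round(est.rho, 4),
                    "sigma": round(est.sigma, 4),
                    "age_ky": round(est.age_years / 1000.0, 2),
                    "ci_lo_ky": round(est.ci95_years[0] / 1000.0, 2),
                    "ci_hi_ky": round(est.ci95_years[1] / 1000.0, 2),
                    "n_defining": len(tree_fixture.nodes[name].motif),
                }
            )
        ages_path = outdir / "ages.tsv"
        pd.DataFrame(
            age_rows,
            columns=[
                "haplogroup",
                "n",
                "rho",
                "sigma",
                "age_ky",
                "ci_lo_ky",
                "ci_hi_ky",
                "n_defining",
            ],
        ).to_csv(ages_path, sep="\t", index=False)
        manifest["outputs"].append(str(ages_path))

    with stage("geography"):
        ranges = []
        centers_rows = []
        for name in sorted(by_group):
            points = [h.origin for h in by_group[name] if h.origin is not None]
            if not points:
                continue
            rng_obj = compute_range(name, points)
            ranges.append(rng_obj)
            centers_rows.append(
                {
                    "haplogroup": name,
                    "n_points": len(points),
                    "center_lat": round(rng_obj.center.latitude, 4),
                    "center_lon": round(rng_obj.center.longitude, 4),
                }
            )
        geojson_path = outdir / "ranges.geojson"
        geojson_path.write_text(json.dumps(ranges_to_geojson(ranges), indent=1, sort_keys=True))
        centers_path = outdir / "centers.tsv"
        pd.DataFrame(
            centers_rows, columns=["haplogroup", "n_points", "center_lat", "center_lon"]
        ).to_csv(centers_path, sep="\t", index=False)
        manifest["outputs"] += [str(geojson_path), str(centers_path)]

    with stage("route_test"):
        model = load_anchor_model(cfg.anchors)
        route_results = {}
        for route_name in sorted(cfg.routes):
            observations = read_route_table(cfg.routes[route_name])
            result = concordance_test(observations, model)
            route_results[route_name] = {
                "n_concordant": result.n_concordant,
                "n_discordant": result.n_discordant,
                "tau": round(result.tau, 4),
                "pearson_r": round(result.pearson_r, 4),
                "pearson_p": round(result.pearson_p, 6),
            }
        routes_path = outdir / "route_tests.json"
        routes_path.write_text(json.dumps(route_results, indent=1, sort_keys=True))
        manifest["outputs"].append(str(routes_path))

    config_repr = json.dumps(
        {
            "input_table": str(cfg.input_table),
            "epsilon": cfg.epsilon,
            "calibration": [cfg.calibration_mode, cfg.calibration_rate],
            "routes": {k: str(v) for k, v in sorted(cfg.routes.items())},
            "seed": cfg.seed,
            "min_clade_size": cfg.min_clade_size,
        },
        sort_keys=True,
    )
    manifest["config_sha256"] = hashlib.sha256(config_repr.encode()).hexdigest()
    manifest["timers_s"] = timers
    manifest["total_s"] = round(time.perf_counter() - t_start, 3)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def simulate_and_date(cfg) -> tuple:
    """simulate -> evolve -> network -> resolve -> date, with ground truth.

    The workhorse behind parameter-recovery checks: returns the
    AgeEstimate for the simulated clade (rooted on the known ancestral
    state) together with the simulation truth record.
    """
    from .synthetic_data import evolve_haplotypes, simulate_tree

    tree = simulate_tree(cfg)
    haps, truth = evolve_haplotypes(tree, cfg)
    net = build_mj_network(haps, epsilon=0, outgroup=())
    net = mp_prune(net)
    rtree = resolve_reticulations(net, outgroup=())
    cal = Calibration(mode="linear", rate=cfg.rate)
    est = date_clade(rtree, cal, clade="sim")
    return est, truth
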