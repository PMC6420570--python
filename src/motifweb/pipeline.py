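"""End-to-end runner: simulate/read -> build -> profile -> analyse, with provenance.

A run is driven by one :class:`RunConfig` (YAML-serialisable).  Every
stochastic stage derives its seeds deterministically from the global seed, so
the same config and seed reproduce every output byte for byte.  A manifest
(JSON) records the config snapshot, package version, per-output SHA-256
hashes and timestamps, which is enough for an exact rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import CommunityValidationError, read_community, write_community
from .motifs import MOTIF_CODES, OTHER_CODES
from .profiles import profile_pipeline
from .synthetic import GeneratorConfig, generate_community
from .trends import fit_all_trends, summarize_profiles
from .webs import ScalarConfig, build_probabilistic_web, diversity_scaled_scalars

log = logging.getLogger("motifweb")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    global_seed: int = 0
    alpha: float = 5000.0
    beta: float = 100.0
    iterations: int = 50
    R: int = 250
    trades_factor: int = 5
    scenario_strength: float = 0.0
    source: str = "simulate"  # or "read"
    data_dir: str | None = None  # for source="read"
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise CommunityValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_or_simulate(cfg: RunConfig):
    """Return (nodes, links, design) from files or from the generator."""
    if cfg.source == "read":
        if not cfg.data_dir:
            raise CommunityValidationError("source='read' requires data_dir")
        d = cfg.data_dir
        return read_community(
            os.path.join(d, "traits.tsv"),
            os.path.join(d, "abundance.tsv"),
            os.path.join(d, "metaweb.tsv"),
            os.path.join(d, "design.tsv"),
        )
    gen = GeneratorConfig(global_seed=cfg.global_seed, **cfg.generator)
    return generate_community(gen)


def compute_tables(
    nodes,
    links,
    design,
    cfg: RunConfig,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the web/census/null/profile stages over every plot-period.

    Returns ``(counts_table, profiles_table)``.  Counts are iteration means
    per scope; profiles carry iteration-mean z and normalised scores.
    """
    base = ScalarConfig(cfg.alpha, cfg.beta)
    count_rows, prof_rows = [], []
    t0 = time.time()
    for k, sample in enumerate(design.samples):
        scalars = diversity_scaled_scalars(base, sample.sown_richness, cfg.scenario_strength)
        try:
            pweb = build_probabilistic_web(sample, nodes, links, scalars)
        except CommunityValidationError as err:
            log.warning("skipping %s/%s: %s", sample.plot_id, sample.time_period, err)
            continue
        full, free = profile_pipeline(
            pweb,
            iterations=cfg.iterations,
            R=cfg.R,
            global_seed=cfg.global_seed,
            trades_factor=cfg.trades_factor,
        )
        for prof in (full, free):
            row = {
                "plot_id": prof.plot_id,
                "time_period": prof.time_period,
                "scope": prof.scope,
                **dict(zip(MOTIF_CODES, prof.counts.tolist())),
            }
            row["other"] = float(sum(row[c] for c in OTHER_CODES))
            row["total"] = float(prof.counts.sum())
            count_rows.append(row)
            for i, cls in enumerate(MOTIF_CODES):
                prof_rows.append(
                    {
                        "plot_id": prof.plot_id,
                        "time_period": prof.time_period,
                        "scope": prof.scope,
                        "motif": cls,
                        "z_mean": prof.z[i],
                        "n_mean": prof.n[i],
                        "n_se": prof.n_se[i],
                        "flags": prof.n_flagged,
                    }
                )
        if progress and (k + 1) % 20 == 0:
            log.info("profiled %d/%d plot-periods (%.1fs)", k + 1, len(design.samples),
                     time.time() - t0)
    return pd.DataFrame(count_rows), pd.DataFrame(prof_rows)


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write all result tables plus a manifest.

    Returns a dict with the in-memory DataFrames and the manifest path.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    stage = "simulate/read"
    try:
        nodes, links, design = load_or_simulate(cfg)
        data_paths = write_community(nodes, links, design, os.path.join(cfg.out_dir, "data"))
        stage = "build/census/null/profile"
        counts, profiles = compute_tables(nodes, links, design, cfg, progress=True)
        stage = "analyze"
        design_df = design.design_frame()
        trends, skipped = fit_all_trends(counts, profiles, design_df)
        summary = summarize_profiles(counts, profiles, design_df)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err

    paths = {}
    for name, df in (
        ("counts", counts), ("profiles", profiles), ("trends", trends),
        ("summaries", summary), ("design", design_df),
    ):
        p = os.path.join(cfg.out_dir, f"{name}.tsv")
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        paths[name] = p
    paths.update(data_paths)

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "global_seed": cfg.global_seed,
        "skipped_responses": skipped,
        "outputs": {name: {"path": p, "sha256": _sha256(p)} for name, p in paths.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    mpath = os.path.join(cfg.out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "counts": counts,
        "profiles": profiles,
        "trends": trends,
        "summary": summary,
        "design": design_df,
        "manifest_path": mpath,
        "out_dir": cfg.out_dir,
    }
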