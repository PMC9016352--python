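"""End-to-end variant comparison: build LCD variants, run slab simulations,
extract phase metrics, rank variants, and write a reproducible report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import trajio
from .forcefield import ForceField, make_forcefield
from .phase import PhaseMetrics, compute_phase_metrics, density_profile, rank_variants
from .sequences import canonical_variant_spec, tdp43_lcd
from .simulate import initialize_compact, run_langevin, slab_schedule
from .system import Trajectory

__all__ = ["RunConfig", "Report", "VariantResult", "validate_config",
           "run_phase_pipeline"]

log = logging.getLogger("lcdphase.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Fully explicit configuration of a variant-comparison run."""

    variants: tuple[str, ...] = ("Wt", "12D", "12A", "5pS", "12pS")
    seeds: tuple[int, ...] = (1, 2, 3)
    preset: str = "desk"
    temperature: float = 310.0
    ionic_strength: float = 0.1
    # system-size overrides (None -> preset values)
    n_chains: int | None = None
    box: tuple[float, float, float] | None = None
    sub_lz: float | None = None
    equilibration_steps: int | None = None
    production_steps: int | None = None
    stride: int = 2000
    cutoff_vdw: float = 25.0
    cutoff_elec: float = 35.0
    # analysis
    n_bins: int = 120
    discard_fraction: float = 0.5
    dense_halfwidth: float = 50.0
    dilute_margin: float = 250.0
    peak_ratio_threshold: float = 10.0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("variants", "seeds", "box"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(config: RunConfig) -> RunConfig:
    """Check a config before any compute; raises ValueError listing every
    problem found."""
    errors = []
    if len(config.variants) < 1:
        errors.append("at least one variant required")
    if len(set(config.variants)) != len(config.variants):
        errors.append("duplicate variant names")
    for name in config.variants:
        try:
            canonical_variant_spec(name)
        except ValueError as exc:
            errors.append(str(exc))
    if not config.seeds:
        errors.append("at least one seed required")
    if config.preset not in ("desk", "paper"):
        errors.append(f"unknown preset {config.preset!r}")
    if config.dense_halfwidth >= config.dilute_margin:
        errors.append("dense_halfwidth must be < dilute_margin")
    if not 0.0 <= config.discard_fraction < 1.0:
        errors.append("discard_fraction must be in [0, 1)")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return config


@dataclass
class VariantResult:
    name: str
    per_seed: list[PhaseMetrics]

    @property
    def c_dilute_mean(self) -> float:
        return float(np.mean([m.c_dilute for m in self.per_seed]))

    @property
    def c_dilute_sd(self) -> float:
        return float(np.std([m.c_dilute for m in self.per_seed]))

    @property
    def c_dense_mean(self) -> float:
        return float(np.mean([m.c_dense for m in self.per_seed]))

    @property
    def condensate_fraction(self) -> float:
        return float(np.mean([m.has_condensate for m in self.per_seed]))

    def consensus_metrics(self) -> PhaseMetrics:
        first = self.per_seed[0]
        dgs = [m.delta_g_trans for m in self.per_seed
               if m.delta_g_trans is not None]
        return PhaseMetrics(
            name=self.name,
            c_dense=self.c_dense_mean,
            c_dilute=self.c_dilute_mean,
            delta_g_trans=float(np.mean(dgs)) if dgs else None,
            has_condensate=self.condensate_fraction >= 0.5,
            dense_halfwidth=first.dense_halfwidth,
            dilute_margin=first.dilute_margin,
        )


@dataclass
class Report:
    config_hash: str
    results: list[VariantResult]
    ranking: list[list[str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "ranking": self.ranking,
                "variants": {
                    r.name: {
                        "c_dilute_mean_mg_ml": r.c_dilute_mean,
                        "c_dilute_sd_mg_ml": r.c_dilute_sd,
                        "c_dense_mean_mg_ml": r.c_dense_mean,
                        "condensate_fraction": r.condensate_fraction,
                        "per_seed": [dataclasses.asdict(m) for m in r.per_seed],
                    }
                    for r in self.results
                },
            },
            indent=2,
        )


def _simulate_variant(
    name: str, seed: int, config: RunConfig, ff: ForceField, outdir: Path | None
) -> Trajectory:
    cache = (
        outdir / f"{name}_seed{seed}.npz" if outdir is not None else None
    )
    if cache is not None and cache.exists():
        log.info("reusing cached trajectory %s", cache)
        return trajio.load_npz(cache)
    overrides = {
        k: v
        for k, v in {
            "n_chains": config.n_chains,
            "box": config.box,
            "sub_lz": config.sub_lz,
            "equilibration_steps": config.equilibration_steps,
            "production_steps": config.production_steps,
        }.items()
        if v is not None
    }
    params, schedule = slab_schedule(
        config.preset, seed=seed, temperature=config.temperature,
        stride=config.stride, **overrides,
    )
    seq = tdp43_lcd(name)
    box = params["box"]
    sub_box = (box[0], box[1], params["sub_lz"])
    log.info("variant %s seed %d: %d chains, box %s", name, seed,
             params["n_chains"], box)
    init = initialize_compact(
        params["n_chains"], seq, ff, sub_box, seed=seed,
        box=(box[0], box[1], params["sub_lz"]),
    )
    traj = run_langevin(init, ff, schedule)
    if cache is not None:
        trajio.save_npz(traj, cache)
    return traj


def run_phase_pipeline(config: RunConfig) -> Report:
    """Run the variant-comparison pipeline and return the report.

    Deterministic given the config's seeds; per-variant trajectories are
    cached in the output directory and reused on rerun.
    """
    config = validate_config(config)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2)
        )
    ff = make_forcefield(
        temperature=config.temperature,
        ionic_strength=config.ionic_strength,
        cutoff_vdw=config.cutoff_vdw,
        cutoff_elec=config.cutoff_elec,
    )
    results = []
    for name in config.variants:
        per_seed = []
        for seed in config.seeds:
            try:
                traj = _simulate_variant(name, seed, config, ff, outdir)
                masses = ff.params_for(traj.bead_codes)[0]
                profile = density_profile(
                    traj, masses, n_bins=config.n_bins,
                    discard_fraction=_production_discard(config, traj),
                )
                metrics = compute_phase_metrics(
                    profile, name=f"{name}_seed{seed}",
                    temperature=config.temperature,
                    dense_halfwidth=config.dense_halfwidth,
                    dilute_margin=config.dilute_margin,
                    peak_ratio_threshold=config.peak_ratio_threshold,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage failed for variant {name}, seed {seed}: "
                    f"{exc}"
                ) from exc
            per_seed.append(metrics)
        results.append(VariantResult(name=name, per_seed=per_seed))
    ranking = rank_variants(
        [(r.name, r.consensus_metrics()) for r in results]
    ) if len(results) >= 2 else [[r.name for r in results]]
    report = Report(
        config_hash=config.content_hash(), results=results, ranking=ranking
    )
    if outdir is not None:
        (outdir / "report.json").write_text(report.to_json())
    return report


def _production_discard(config: RunConfig, traj: Trajectory) -> float:
    """Fraction of saved frames to discard: equilibration frames plus the
    configured fraction of production."""
    boxes = traj.boxes
    final_lz = boxes[-1, 2]
    production = np.nonzero(boxes[:, 2] == final_lz)[0]
    first_prod = int(production[0])
    n = traj.n_frames
    keep_from = first_prod + config.discard_fraction * (n - first_prod)
    return min(0.95, keep_from / n)
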