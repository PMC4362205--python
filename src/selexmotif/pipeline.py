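"""End-to-end pipeline: count -> autoseed -> PWM -> dependency -> similarity -> logos.

Configuration is a YAML file (or an equivalent TSV experiment table) listing,
per experiment, the per-cycle read files, the seed (an explicit pattern or
"auto" for the top Autoseed maximum), the cycle to build the model from, the
multinomial order and the flank width; plus global pattern-space bounds and
similarity settings.  All outputs are plain text or SVG, and a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import autoseed as aseed
from . import dependency as dep
from . import io as sio
from . import patterns as pat
from . import similarity as sim
from . import viz

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    experiment_id: str
    cycle_files: dict[int, str]
    seed: str = "auto"
    use_cycle: int | None = None
    background_cycle: int = 0
    multinomial_order: int = 1
    flank: int = 2


@dataclass
class RunConfig:
    experiments: list[ExperimentConfig]
    output_dir: str = "selexmotif_out"
    bounds: pat.PatternBounds = field(default_factory=pat.PatternBounds)
    theta: float = 0.5
    min_count: int = 10
    top_seeds: int = 5
    similarity_k: int = 6
    similarity_max_gap: int = 4
    network_threshold: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        bounds = pat.PatternBounds(**(d.get("bounds") or {}))
        exps = [
            ExperimentConfig(
                experiment_id=str(e["id"]),
                cycle_files={int(k): str(v) for k, v in e["cycles"].items()},
                seed=str(e.get("seed", "auto")),
                use_cycle=e.get("use_cycle"),
                background_cycle=int(e.get("background_cycle", 0)),
                multinomial_order=int(e.get("multinomial_order", 1)),
                flank=int(e.get("flank", 2)),
            )
            for e in d["experiments"]
        ]
        return cls(
            experiments=exps,
            output_dir=str(d.get("output_dir", "selexmotif_out")),
            bounds=bounds,
            theta=float(d.get("theta", 0.5)),
            min_count=int(d.get("min_count", 10)),
            top_seeds=int(d.get("top_seeds", 5)),
            similarity_k=int(d.get("similarity_k", 6)),
            similarity_max_gap=int(d.get("similarity_max_gap", 4)),
            network_threshold=float(d.get("network_threshold", 0.8)),
        )


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and experiment."""


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage for every experiment; returns the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pwms = []
    for exp in config.experiments:
        exp_dir = out / exp.experiment_id
        exp_dir.mkdir(exist_ok=True)
        try:
            pwm = _run_experiment(exp, config, exp_dir)
        except Exception as exc:  # noqa: BLE001 - stage-named rethrow
            raise StageError(f"experiment {exp.experiment_id}: {exc}") from exc
        pwms.append(pwm)
    if len(pwms) >= 2:
        try:
            matrix = sim.motif_similarity_matrix(
                pwms, k=config.similarity_k, max_gap=config.similarity_max_gap
            )
            matrix.to_tsv(out / "motif_similarity.tsv")
            newick = sim.cluster_motifs(matrix)
            (out / "motif_dendrogram.nwk").write_text(newick + "\n")
            g = sim.motif_network(matrix, config.network_threshold)
            sim.write_network(
                g, edge_tsv=out / "motif_network.tsv",
                graphml=out / "motif_network.graphml",
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"cross-experiment similarity: {exc}") from exc
    logger.info("pipeline finished: %s", out)
    return out


def _run_experiment(
    exp: ExperimentConfig, config: RunConfig, exp_dir: Path
):
    cycles = {
        c: sio.CycleReads(exp.experiment_id, c, sio.read_sequences(p))
        for c, p in sorted(exp.cycle_files.items())
    }
    use_cycle = exp.use_cycle if exp.use_cycle is not None else max(cycles)
    reads = cycles[use_cycle]

    table = pat.count_patterns(reads.reads, bounds=config.bounds, cycle=use_cycle)
    pat.write_count_table(table, exp_dir / "counts.tsv")

    cfg = aseed.AutoseedConfig(
        theta=config.theta, min_count=config.min_count,
        bounds=config.bounds, top=config.top_seeds,
    )
    maxima = aseed.find_local_maxima(table, cfg)
    if not maxima:
        raise ValueError("no local maxima found")
    models = aseed.pick_primary_and_secondary(maxima)
    aseed.write_seed_table(models, exp_dir / "seeds.tsv")

    if exp.seed == "auto":
        seed = models[0].pattern
    else:
        seed = pat.parse_pattern(exp.seed)
    bg = cycles.get(exp.background_cycle)
    from .pwm import build_pwm

    pwm = build_pwm(
        reads, seed,
        order=exp.multinomial_order, flank=exp.flank,
        background_reads=bg,
        background_mode="cycle0" if bg is not None else "none",
        name=exp.experiment_id,
    )
    pwm.to_file(exp_dir / "pwm.tsv")
    sio.write_pwm_meme(pwm.frequencies, exp_dir / "pwm.meme", name=exp.experiment_id)

    table_dep = dep.dependency_table(reads, seed, flank=exp.flank)
    table_dep.to_tsv(exp_dir / "dependency.tsv")

    (exp_dir / "barcode_logo.svg").write_text(viz.barcode_logo(pwm))
    (exp_dir / "sequence_logo.svg").write_text(viz.sequence_logo(pwm))
    (exp_dir / "dependency_heatmap.svg").write_text(viz.dependency_heatmap(table_dep))
    return pwm
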