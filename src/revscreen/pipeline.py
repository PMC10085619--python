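"""End-to-end pipeline orchestration.

A :class:`RunConfig` (YAML/JSON-loadable, schema-validated, unknown keys
rejected) describes which stages to run and with what parameters; the
canonical stage order is

    simulate -> fc -> signature -> screen -> validate -> deg -> ora -> metrics

Each stage writes its outputs under ``<outdir>/<run_id>/`` and the run ends
with a ``manifest.json`` recording the config echo, library versions, and
per-output SHA-256 checksums and row counts — re-running the same config on
the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .diffexpr import DEConfig, ExpressionMatrix, compute_fc
from .enrichment import load_gmt, ora
from .errors import RevScreenError, ValidationError
from .metrics import add_tumor_volumes
from .reversal import AgentLibrary, screen_library, validate_reversal
from .signatures import (
    SignatureConfig,
    extract_signature,
    load_fc_profile,
)
from .simulate import (
    SimulationConfig,
    simulate_agent_library,
    simulate_correlated_fc,
    simulate_expression,
    simulate_gene_sets,
)

__all__ = ["RunConfig", "StageError", "run_pipeline", "STAGE_ORDER"]

STAGE_ORDER = (
    "simulate", "fc", "signature", "screen", "validate", "deg", "ora", "metrics",
)


class StageError(RevScreenError):
    """A stage failed; the message is prefixed with the stage name."""


class SimulationParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = 5000
    n_case: int = 10
    n_control: int = 10
    de_fraction: float = 0.10
    de_log2fc_mean: float = 1.5
    de_log2fc_sd: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    n_agents: int = 200
    n_reversers: int = 20
    n_mimickers: int = 20
    reversal_strength: float = 0.8
    agent_noise_sd: float = 0.3
    n_gene_sets: int = 20
    set_size_range: tuple[int, int] = (20, 100)
    validate_target_rho: float = -0.2


class InputPaths(BaseModel):
    model_config = ConfigDict(extra="forbid")
    matrix: Optional[str] = None
    design: Optional[str] = None
    disease_fc: Optional[str] = None
    library: Optional[str] = None  # long-format TSV or directory
    treatment_fc: Optional[str] = None
    gmt: Optional[str] = None
    measurements: Optional[str] = None


class RunConfig(BaseModel):
    """Fully serializable description of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    run_id: str = "run"
    outdir: str = "runs"
    seed: int = 0
    stages: list[str] = Field(
        default_factory=lambda: ["simulate", "fc", "signature", "screen",
                                 "validate", "deg", "ora"]
    )
    up_threshold: float = 1.50
    down_threshold: float = 0.67
    deg_up_threshold: float = 2.0
    deg_down_threshold: float = 0.5
    pseudocount: float = 1.0
    mean_type: str = "arithmetic"
    library_size_normalize: bool = False
    fisher_sided: str = "two"
    spearman_universe: str = "shared"
    validate_alpha: float = 0.05
    simulation: SimulationParams = Field(default_factory=SimulationParams)
    inputs: InputPaths = Field(default_factory=InputPaths)

    def model_post_init(self, __context: Any) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.model_validate(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _row_count(path: Path) -> int:
    if path.suffix in (".tsv", ".txt", ".gmt"):
        return sum(1 for _ in path.open())
    return 1


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and return the run manifest."""
    run_dir = Path(config.outdir) / config.run_id
    run_dir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in config.stages]
    sig_config = SignatureConfig(config.up_threshold, config.down_threshold)
    deg_config = SignatureConfig(config.deg_up_threshold, config.deg_down_threshold)
    outputs: dict[str, dict] = {}
    state: dict[str, Any] = {}

    def emit(stage: str, name: str, path: Path) -> None:
        outputs.setdefault(stage, {})[name] = {
            "path": str(path.relative_to(run_dir)),
            "sha256": _sha256(path),
            "rows": _row_count(path),
        }

    for stage in stages:
        try:
            _run_stage(stage, config, sig_config, deg_config, run_dir, state, emit)
        except RevScreenError as exc:
            raise StageError(f"[{stage}] {exc}") from exc

    manifest = {
        "run_id": config.run_id,
        "config": json.loads(config.model_dump_json()),
        "stages_run": stages,
        "outputs": outputs,
        "versions": _versions(),
    }
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _versions() -> dict[str, str]:
    import numpy, scipy, statsmodels  # noqa: E401

    return {
        "revscreen": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _require_input(config: RunConfig, field: str, stage: str) -> Path:
    value = getattr(config.inputs, field)
    if value is None:
        raise StageError(
            f"[{stage}] missing input {field!r} and no simulate stage provided it"
        )
    path = Path(value)
    if not path.exists():
        raise StageError(f"[{stage}] input {field!r} not found: {path}")
    return path


def _run_stage(stage, config, sig_config, deg_config, run_dir, state, emit) -> None:
    sim = config.simulation

    if stage == "simulate":
        sim_config = SimulationConfig(
            n_genes=sim.n_genes, n_case=sim.n_case, n_control=sim.n_control,
            de_fraction=sim.de_fraction, de_log2fc_mean=sim.de_log2fc_mean,
            de_log2fc_sd=sim.de_log2fc_sd, noise_sd=sim.noise_sd,
            baseline_mean=sim.baseline_mean, baseline_sd=sim.baseline_sd,
            n_agents=sim.n_agents, n_reversers=sim.n_reversers,
            n_mimickers=sim.n_mimickers, reversal_strength=sim.reversal_strength,
            agent_noise_sd=sim.agent_noise_sd, seed=config.seed,
        )
        matrix, truth = simulate_expression(sim_config)
        library, labels = simulate_agent_library(truth, sim_config)
        state.update(matrix=matrix, truth=truth, library=library, agent_labels=labels)
        matrix.to_tsv(run_dir / "matrix.tsv", run_dir / "design.tsv")
        library.to_long_tsv(run_dir / "library.tsv")
        truth_out = {
            "log2fc": {g: round(float(v), 6) for g, v in truth["log2fc"].items()},
            "agent_labels": labels,
        }
        (run_dir / "truth.json").write_text(
            json.dumps(truth_out, indent=2, sort_keys=True) + "\n"
        )
        for name in ("matrix.tsv", "design.tsv", "library.tsv", "truth.json"):
            emit(stage, name, run_dir / name)

    elif stage == "fc":
        if "matrix" not in state:
            matrix_path = _require_input(config, "matrix", stage)
            design_path = _require_input(config, "design", stage)
            state["matrix"] = ExpressionMatrix.from_tsv(matrix_path, design_path)
        de_config = DEConfig(
            pseudocount=config.pseudocount,
            mean_type=config.mean_type,
            library_size_normalize=config.library_size_normalize,
        )
        profile = compute_fc(state["matrix"], de_config)
        state["disease_fc"] = profile
        profile.to_tsv(run_dir / "disease_fc.tsv")
        emit(stage, "disease_fc.tsv", run_dir / "disease_fc.tsv")

    elif stage == "signature":
        profile = _disease_fc(config, state, stage)
        signature = extract_signature(profile, sig_config)
        state["signature"] = signature
        signature.to_json(run_dir / "signature.json")
        emit(stage, "signature.json", run_dir / "signature.json")

    elif stage == "screen":
        profile = _disease_fc(config, state, stage)
        if "library" not in state:
            lib_path = _require_input(config, "library", stage)
            state["library"] = (
                AgentLibrary.from_directory(lib_path)
                if lib_path.is_dir()
                else AgentLibrary.from_long_tsv(lib_path)
            )
        result = screen_library(
            profile, state["library"], sig_config,
            sided=config.fisher_sided, universe=config.spearman_universe,
        )
        state["screen"] = result
        result.to_tsv(run_dir / "screen.tsv")
        (run_dir / "screen_excluded.txt").write_text(
            "".join(f"{a}\n" for a in result.excluded)
        )
        emit(stage, "screen.tsv", run_dir / "screen.tsv")
        emit(stage, "screen_excluded.txt", run_dir / "screen_excluded.txt")

    elif stage == "validate":
        profile = _disease_fc(config, state, stage)
        if config.inputs.treatment_fc is not None:
            treatment = load_fc_profile(
                _require_input(config, "treatment_fc", stage), contrast_id="treatment"
            )
        elif "truth" in state:
            treatment = simulate_correlated_fc(
                profile, sim.validate_target_rho,
                seed=config.seed, contrast_id="simulated_treatment",
            )
        else:
            raise StageError(f"[{stage}] needs a treatment_fc input or the simulate stage")
        res = validate_reversal(treatment, profile, alpha=config.validate_alpha)
        state["validation"] = res
        payload = {
            "rho": round(res.rho, 6), "p": res.p,
            "n_shared": res.n_shared, "label": res.label,
        }
        (run_dir / "validation.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        emit(stage, "validation.json", run_dir / "validation.json")

    elif stage == "deg":
        profile = _disease_fc(config, state, stage)
        degs = extract_signature(profile, deg_config).genes
        state["degs"] = degs
        (run_dir / "degs.txt").write_text("".join(f"{g}\n" for g in sorted(degs)))
        emit(stage, "degs.txt", run_dir / "degs.txt")

    elif stage == "ora":
        if "degs" not in state:
            raise StageError(f"[{stage}] requires the deg stage")
        if config.inputs.gmt is not None:
            collection = load_gmt(_require_input(config, "gmt", stage))
        elif "disease_fc" in state:
            universe = sorted(state["disease_fc"].genes)
            collection = simulate_gene_sets(
                sim.n_gene_sets, sim.set_size_range, universe,
                enriched_in=set(state["degs"]), seed=config.seed,
            )
        else:
            raise StageError(f"[{stage}] needs a gmt input or an in-run universe")
        results = ora(state["degs"], collection)
        state["ora"] = results
        pd.DataFrame(
            [
                {
                    "set_name": r.set_name, "overlap": r.overlap_count,
                    "set_size": r.set_size, "degs_in_universe": r.degs_in_universe,
                    "universe_size": r.universe_size, "p": r.p, "q": r.q,
                }
                for r in results
            ]
        ).to_csv(run_dir / "ora.tsv", sep="\t", index=False, float_format="%.6g")
        emit(stage, "ora.tsv", run_dir / "ora.tsv")

    elif stage == "metrics":
        path = _require_input(config, "measurements", stage)
        table = pd.read_csv(path, sep="\t", comment="#")
        out = add_tumor_volumes(table)
        out.to_csv(run_dir / "measurements_volumes.tsv", sep="\t",
                   index=False, float_format="%.6g")
        emit(stage, "measurements_volumes.tsv", run_dir / "measurements_volumes.tsv")


def _disease_fc(config: RunConfig, state: dict, stage: str):
    if "disease_fc" not in state:
        path = _require_input(config, "disease_fc", stage)
        state["disease_fc"] = load_fc_profile(path, contrast_id="disease")
    return state["disease_fc"]
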