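"""Simulate the study's inputs: a case/control expression matrix with
planted differential expression and an agent library with planted
reversers, mimickers and null agents.

Writes the matrix/design/library/truth files under scratch/study/ (they
are large) and a small summary under results/analysis/.
"""

import json
from pathlib import Path

from revscreen import SimulationConfig, simulate_agent_library, simulate_expression

SEED = 1
SCRATCH = Path("scratch/study")
RESULTS = Path("results/analysis")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    config = SimulationConfig(seed=SEED)
    matrix, truth = simulate_expression(config)
    library, labels = simulate_agent_library(truth, config)

    matrix.to_tsv(SCRATCH / "matrix.tsv", SCRATCH / "design.tsv")
    library.to_long_tsv(SCRATCH / "library.tsv")
    truth.to_csv(SCRATCH / "truth.tsv", sep="\t", float_format="%.6g")
    (SCRATCH / "agent_labels.json").write_text(json.dumps(labels, indent=2) + "\n")

    summary = {
        "seed": SEED,
        "n_genes": config.n_genes,
        "n_case": config.n_case,
        "n_control": config.n_control,
        "n_planted_de": int(truth["is_de"].sum()),
        "n_agents": len(library),
        "n_reversers": config.n_reversers,
        "n_mimickers": config.n_mimickers,
    }
    (RESULTS / "01_simulation_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(f"simulated {config.n_genes} genes x "
          f"{config.n_case}+{config.n_control} samples; "
          f"{summary['n_planted_de']} planted DE genes; "
          f"{len(library)} agents ({config.n_reversers} reversers, "
          f"{config.n_mimickers} mimickers)")
    print(f"wrote inputs to {SCRATCH}/")


if __name__ == "__main__":
    main()
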