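"""Screen the agent library against the disease profile and rank agents by
anti-correlation (ascending Spearman rho, ties by odds ratio).

The planted reversers should dominate the top of the ranking; the table of
the ten best-ranked agents and the full screen are written under
results/analysis/.
"""

import json
from pathlib import Path

from revscreen import AgentLibrary, load_fc_profile, screen_library

SCRATCH = Path("scratch/study")
RESULTS = Path("results/analysis")


def main() -> None:
    disease_fc = load_fc_profile(SCRATCH / "disease_fc.tsv", contrast_id="disease")
    library = AgentLibrary.from_long_tsv(SCRATCH / "library.tsv")
    labels = json.loads((SCRATCH / "agent_labels.json").read_text())

    result = screen_library(disease_fc, library)
    result.to_tsv(RESULTS / "03_screen.tsv")
    result.to_dataframe().head(10).to_csv(
        RESULTS / "03_top10_agents.tsv", sep="\t", index=False, float_format="%.6g"
    )

    top20 = [s.agent_id for s in result.top(20)]
    precision = sum(labels[a] == "reverser" for a in top20) / 20
    print(f"screened {len(result)} agents "
          f"({len(result.excluded)} excluded for zero signature overlap)")
    print("top 10 by ascending rho:")
    for s in result.top(10):
        print(f"  {s.rank:>2}. {s.agent_id:<14} rho={s.rho:+.3f} "
              f"OR={s.odds_ratio:.4f} q={s.rho_q:.2e} [{labels[s.agent_id]}]")
    print(f"top-20 precision for planted reversers: {precision:.2f}")


if __name__ == "__main__":
    main()
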