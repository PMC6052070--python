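"""Sterol-domain statistics and the cross-system Welch comparison.

Reads the replicate grids written by 04_monolayer_simulation.py, labels sterol
domains with image-analysis conventions (8-connectivity, clipped boundary),
computes each replicate's relative mean domain size, and compares the two
systems with a Welch two-sample test on the log values.
"""

import argparse
from pathlib import Path

from saposim.bigmonolayer import read_grid_text
from saposim.domains import compare_systems, domain_stats, label_domains


def replicate_stats(sysdir: Path, sterol: str):
    out = []
    for p in sorted(sysdir.glob("rep*.grid.txt")):
        state = read_grid_text(p)
        lab = label_domains(state, [sterol], connectivity=8, boundary="clipped")
        out.append(domain_stats(lab))
    return out


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--grids", type=Path, default=Path("results/monolayer"))
    ap.add_argument("--out", type=Path, default=Path("results/domains"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    chol = replicate_stats(args.grids / "cholesterol_system", "CHOL")
    d7 = replicate_stats(args.grids / "delta7_system", "DELTA7")
    res, table = compare_systems(chol, d7, "cholesterol_system", "delta7_system")
    table.to_csv(args.out / "domain_stats.csv", index=False)

    g = table.groupby("system")
    for system, grp in g:
        print(
            f"{system}: {grp['n_domains'].mean():6.1f} domains of mean size "
            f"{grp['mean_size'].mean():6.1f} cells, "
            f"relative mean size {grp['relative_mean_size'].mean():.4f}"
        )
    print(
        f"Welch two sample test on log relative mean size: "
        f"t = {res.statistic:.3f}, df = {res.df:.4f}, p = {res.p_value:.3e}"
    )
    larger = "cholesterol_system" if res.statistic > 0 else "delta7_system"
    print(f"larger relative mean sterol-domain size: {larger}")


if __name__ == "__main__":
    main()
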