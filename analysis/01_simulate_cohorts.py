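"""Generate the two synthetic surgical cohorts and summarise them.

Draws the pre-operative (n=47: 15 AVR / 15 Ozaki / 13 Ross / 4 VS) and
post-operative (n=35: 12/10/10/3) cohorts, checks the realised
ascending-aorta surface areas against their configured group targets,
and writes the subject manifests.  Full per-subject STL meshes go to
scratch/ (they are bulky and reproducible from the seed).
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

import aorta_ssm as a  # noqa: E402

SEED = 1


def summarise(name: str, cfg) -> None:
    pop = a.sample_population(cfg)
    RESULTS.mkdir(exist_ok=True)
    pop.covariates.to_csv(RESULTS / f"{name}_manifest.csv", index=False)
    pop.write_stl_dir(SCRATCH / f"{name}_stl")
    stats = pop.covariates.groupby("group")["surface_area_mm2"].agg(
        ["count", "mean", "std"]
    )
    print(f"\n{name} cohort ({pop.n_subjects} subjects):")
    print(stats.round(0).to_string())
    print("configured targets:")
    for g, s in cfg.groups.items():
        print(f"  {g:6s} n={s.n_subjects:3d}  {s.area_mean:8.0f} ± {s.area_sd:.0f} mm²"
              f"  BAV fraction {s.bav_fraction:.2f}")
    valve = pop.covariates.groupby(["group", "valve_type"]).size()
    print("valve morphotypes:")
    print(valve.to_string())


def main() -> None:
    summarise("preop", a.preop_cohort(seed=SEED))
    summarise("postop", a.postop_cohort(seed=SEED + 1))
    print(f"\nmanifests written to {RESULTS}, STL meshes to {SCRATCH}")


if __name__ == "__main__":
    sys.exit(main())
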