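#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes MRM peak tables for the replete, mutant-panel and starvation
scenarios, one replete and one starved microscope field, and the paired
concentration/relocation time courses, all under results/fixtures/.
"""

from pathlib import Path

from ippdyn import synthetic

OUT = Path("results/fixtures")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    scenarios = [
        synthetic.wt_replete_scenario(),
        synthetic.mutants_replete_scenario(),
        synthetic.wt_starvation_scenario(),
        synthetic.vip1d_starvation_scenario(),
        # a noisy replicate set matching the assay's n=4 design
        synthetic.wt_replete_scenario(replicate_cv=0.15, n_replicates=4, seed=21),
    ]
    for sc in scenarios:
        peaks_path, truth_path = synthetic.write_ms_fixture(sc, OUT)
        print(f"{sc.name}: {peaks_path.name} ({truth_path.name})")

    for name, spec in [
        ("field_replete", synthetic.replete_field_spec(seed=7)),
        ("field_starved", synthetic.starved_field_spec(seed=7)),
    ]:
        paths = synthetic.write_image_fixture(spec, OUT, name)
        print(f"{name}: {paths['images'].name} + truth")

    for strain in ("vip1d", "wt"):
        conc, reloc = synthetic.generate_relocation_timecourse(seed=0, strain=strain)
        conc.to_csv(OUT / f"{strain}_conc_timecourse.csv", index=False)
        reloc.to_csv(OUT / f"{strain}_reloc_timecourse.csv", index=False)
        print(f"{strain}: concentration + relocation time courses")


if __name__ == "__main__":
    main()
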