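"""Generate and archive one instance of every synthetic input the pipeline
consumes: a two-population phased haplotype panel (VCF + sample map +
genetic map), a phylogenetic allele-frequency cline, a donor-structured
single-nucleus expression cohort (MTX), and a BMI-discordant twin cohort.

Writes to results/data/.  All downstream scripts regenerate what they need
at their own problem sizes; this script documents the exchange formats and
verifies the round trips.
"""

from pathlib import Path

import numpy as np

from clinesel import io, simulate, workflows

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260922


def main() -> None:
    # -- haplotype panel: Finland-like isolate plus a sister population.
    # Small demonstration panel; seeds are retried until the focal derived
    # allele segregates in both populations (the same conditioning the
    # selection workflows apply, since a lost allele has no haplotype story).
    pops = [
        simulate.PopulationSpec("FIN", 50, latitude=61.9, mean_annual_temp=1.7),
        simulate.PopulationSpec("GBR", 50, latitude=52.4, mean_annual_temp=9.8,
                                split_parent="FIN", split_generation=0),
    ]
    for attempt in range(100):
        cfg = simulate.SimulationConfig(
            n_sites=120, focal_site_index=60, generations=100, seed=SEED + attempt,
            selection_coefficient=0.08, sweep_start_generation=30,
            focal_single_origin=True, initial_focal_freq=0.1,
        )
        ps = simulate.simulate_haplotype_panel(pops, cfg)
        freqs = [ps.panels[p.name].derived_frequency(60) for p in pops]
        if all(0.1 < f < 0.9 for f in freqs):
            break
    io.write_vcf(ps.panels, OUT / "panel.vcf")
    io.write_sample_populations(ps.panels, OUT / "sample_populations.tsv")
    io.write_genetic_map(ps.panels["FIN"], OUT / "genetic_map.tsv")
    for name, panel in ps.panels.items():
        print(f"{name}: {panel.n_haplotypes} haplotypes x {panel.n_sites} sites; "
              f"focal derived frequency {panel.derived_frequency(60):.3f} "
              f"(lost: {ps.focal_lost[name]})")

    # -- cline over a 22-population tree
    tree = workflows.random_population_tree(SEED)
    lat = {t.name: v for t, v in zip(sorted(tree.tips(), key=lambda t: t.name),
                                     np.linspace(0, 65, 22))}
    ds = simulate.simulate_cline(tree, lat, slope=0.08, bm_sigma2=0.1,
                                 intercept=-2.0, seed=SEED)
    ds.to_csv(OUT / "cline.tsv", sep="\t")
    tree.write(str(OUT / "population_tree.nwk"))
    print(f"cline: {len(ds)} populations, frequency range "
          f"[{ds.frequency.min():.3f}, {ds.frequency.max():.3f}]")

    # -- single-nucleus cohort with a planted 12-gene trans set
    mat = simulate.simulate_expression_cohort(
        n_donors=12, cells_per_donor=30, n_genes=60, effect=2.0, seed=SEED,
    )
    io.write_expression_cohort(mat, OUT / "snrna_cohort")
    back = io.read_expression_cohort(OUT / "snrna_cohort")
    assert np.array_equal(back.counts, mat.counts), "MTX round trip failed"
    print(f"snRNA cohort: {mat.n_cells} nuclei x {len(mat.genes)} genes, "
          f"{int(mat.donors.risk_carrier.sum())}/{len(mat.donors)} carrier donors")

    # -- twin cohort
    expr, samples = simulate.simulate_twin_cohort(n_pairs=44, target_rho=0.55,
                                                  seed=SEED)
    expr.to_csv(OUT / "twin_expression.tsv", sep="\t")
    samples.to_csv(OUT / "twin_samples.tsv", sep="\t")
    print(f"twin cohort: {len(samples)} individuals in {samples.pair_id.nunique()} "
          f"BMI-discordant pairs")


if __name__ == "__main__":
    main()
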