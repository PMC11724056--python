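"""Generate the synthetic wound-healing study and write it to disk.

Produces the three modalities with planted ground truth under
results/data/: single-cell counts + metadata, WT/KO bulk counts +
design, one Visium-like grid per timepoint with tissue positions, the
ligand-receptor pair table, and truth.json describing what downstream
stages are expected to recover.
"""

import json
from pathlib import Path

from scarscreen import synthdata
from scarscreen.io import write_lr_table, write_mtx, write_spot_positions

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthdata.SynthConfig(seed=SEED)
    counts, meta, truth = synthdata.generate_single_cell(cfg)
    write_mtx(counts, OUT / "sc_counts")
    meta.to_csv(OUT / "cell_meta.tsv", sep="\t", index=False)
    print(f"single cell: {counts.n_genes} genes x {counts.n_obs} cells "
          f"over days {cfg.timepoints}")

    bulk, design = synthdata.generate_bulk(cfg, truth)
    write_mtx(bulk, OUT / "bulk_counts")
    design.frame.to_csv(OUT / "bulk_design.tsv", sep="\t", index=False)
    print(f"bulk: {bulk.n_obs} samples ({cfg.n_bulk_per_genotype} per genotype)")

    for day in cfg.timepoints:
        vis, table = synthdata.generate_visium(cfg, truth, timepoint=day)
        write_mtx(vis, OUT / f"visium_day{day}")
        write_spot_positions(table, OUT / f"tissue_positions_day{day}.csv")
        n_wound = int((table.regions() == "wound").sum())
        print(f"visium day {day}: {vis.n_obs} spots, {n_wound} in the wound disk")

    write_lr_table(synthdata.default_lr_frame(), OUT / "lr_pairs.tsv")
    (OUT / "truth.json").write_text(json.dumps({
        "true_scar_genes": sorted(truth.true_scar_genes),
        "decoy_genes": {k: sorted(v) for k, v in truth.decoy_genes.items()},
        "ko_genes": sorted(truth.ko_genes),
        "anchor_gene": truth.anchor_gene,
        "seed": SEED,
    }, indent=2) + "\n")
    print(f"planted scarring genes: {sorted(truth.true_scar_genes)}")


if __name__ == "__main__":
    main()
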