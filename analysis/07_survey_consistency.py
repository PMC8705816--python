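"""Arithmetic consistency of the published survey tables.

The survey's full dataset (585 RefSeq assemblies and a web-service prophage
predictor) cannot be regenerated offline; its printed per-taxon counts can.
This script recomputes every derivable total and ratio from the per-taxon
tables and writes them to results/published_consistency.tsv.
"""

from pathlib import Path

from bifiphage import published

def main() -> None:
    rows = [
        ("genomes_total", published.total_genomes()),
        ("prophages_total", published.total_prophages()),
        ("prophages_per_genome", round(published.mean_prophages_per_genome(), 2)),
        ("nonredundant_spacers_total", published.total_spacers()),
        ("spacers_per_genome", round(published.mean_unique_spacers_per_genome(), 1)),
        ("blongum_genomes", published.longum_genomes()),
    ]
    out = Path("results")
    out.mkdir(exist_ok=True)
    lines = ["quantity\tvalue"] + [f"{k}\t{v}" for k, v in rows]
    (out / "published_consistency.tsv").write_text("\n".join(lines) + "\n")
    for k, v in rows:
        print(f"{k:28s} {v}")

if __name__ == "__main__":
    main()
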