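"""Score spikelet fertility, summarise the F2 population, select the bulks.

Reads results/sim/phenotypes.tsv (grain counts per plant), recomputes
fertility from the counts, reports the population moments that motivate
bulk selection, and writes the tails (50 + 50 plants) to
results/phenotypes/bulks.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from bulkscan.phenotyping import read_phenotypes, select_bulks, summarize

IN = Path("results/sim/phenotypes.tsv")
OUT = Path("results/phenotypes")
BULK_SIZE = 50


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pheno = read_phenotypes(IN)
    stats = summarize(pheno["fertility_percent"] / 100.0, scale="proportion")
    design = select_bulks(pheno.set_index("plant_id")["fertility_percent"], BULK_SIZE)

    print(f"n = {stats.n} plants; fertility mean {stats.mean:.4f} (proportion), "
          f"SD {stats.sd:.4f}, CV {stats.cv_percent:.2f}%")
    print(f"range {100 * stats.min:.2f}-{100 * stats.max:.2f}%")
    print(f"sensitive bulk ({BULK_SIZE} plants): {design.sensitive_range[0]:.2f}-"
          f"{design.sensitive_range[1]:.2f}%")
    print(f"tolerant  bulk ({BULK_SIZE} plants): {design.tolerant_range[0]:.2f}-"
          f"{design.tolerant_range[1]:.2f}%")

    pd.DataFrame(
        {
            "plant_id": design.tolerant_ids + design.sensitive_ids,
            "bulk": ["T"] * BULK_SIZE + ["S"] * BULK_SIZE,
        }
    ).to_csv(OUT / "bulks.tsv", sep="\t", index=False)
    (OUT / "summary.json").write_text(
        json.dumps(
            {
                "n": stats.n,
                "mean": stats.mean,
                "sd": stats.sd,
                "cv_percent": stats.cv_percent,
                "min": stats.min,
                "max": stats.max,
                "scale": stats.scale,
                "tolerant_range_percent": design.tolerant_range,
                "sensitive_range_percent": design.sensitive_range,
            },
            indent=1,
        )
    )
    print(f"wrote {OUT/'bulks.tsv'} and {OUT/'summary.json'}")


if __name__ == "__main__":
    main()
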