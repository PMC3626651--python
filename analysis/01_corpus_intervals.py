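#!/usr/bin/env python
"""Report the copy-number interval sizes and chromosome dosage fractions.

Loads the packaged breakpoint/copy-number corpus, prints each deletion and
duplication at report precision, and computes the fraction of the
chromosome deleted and duplicated. Writes results/printed_intervals.tsv
and results/dosage.json.
"""

import json
import os

from derivchrom.fixture import load_fixture
from derivchrom.intervals import round_printed, span_length, union_spans
from derivchrom.pipeline import fixture_regions
from derivchrom.reconstruct import dosage_summary

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    corpus = load_fixture()
    rows = []
    for iv, retained in corpus.acgh_deletions:
        bp = span_length(iv, retained)
        unit, dec = ("Mb", 1) if bp >= 1_000_000 else ("kb", 0)
        rows.append(("deletion", iv.start, iv.stop, bp,
                     f"{round_printed(bp, unit, dec)} {unit}",
                     str(retained) if retained else "."))
    for iv in corpus.acgh_duplications:
        bp = span_length(iv)
        unit, dec = ("Mb", 2) if bp >= 1_000_000 else ("kb", 0)
        rows.append(("duplication", iv.start, iv.stop, bp,
                     f"{round_printed(bp, unit, dec)} {unit}", "."))
    with open(os.path.join(OUT, "printed_intervals.tsv"), "w") as fh:
        fh.write("kind\tstart\tstop\tspan_bp\tprinted\tretained\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
            print(*row, sep="\t")

    dosage = dosage_summary(fixture_regions(), corpus.chrom_length)
    summary = {
        "chrom_length": corpus.chrom_length,
        "duplicated_bp": union_spans(corpus.acgh_duplications),
        "fraction_deleted_pct": round(100 * dosage.fraction_deleted, 2),
        "fraction_duplicated_pct": round(100 * dosage.fraction_duplicated, 2),
    }
    with open(os.path.join(OUT, "dosage.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"\ndeleted: {summary['fraction_deleted_pct']}% of the chromosome; "
          f"duplicated: {summary['fraction_duplicated_pct']}%")


if __name__ == "__main__":
    main()
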