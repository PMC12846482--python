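"""Bundled worked-example data: a published genome-wide marker set.

The package ships the significant body-weight loci reported for four
geographic Mandarin fish (*Siniperca chuatsi*) populations, with the
association model(s) that flagged each locus, plus that study's
genome-wide substitution-class counts.  These serve as small real-data
inputs for the multi-model merge and substitution-summary operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: genome-wide counts of the six unordered substitution classes in the
#: final filtered call set (1,939,223 SNPs across 90 fish)
PUBLISHED_SUBSTITUTION_COUNTS: dict[str, int] = {
    "A/G": 562_792,
    "C/T": 561_959,
    "A/C": 207_819,
    "A/T": 252_865,
    "C/G": 146_809,
    "G/T": 206_979,
}


def load_published_loci() -> pd.DataFrame:
    """The published significant-locus table (snp, chrom, pos, ref, alt, method)."""
    path = resources.files("growmark.data") / "bodyweight_significant_loci.tsv"
    df = pd.read_csv(path, sep="\t")
    return df.rename(
        columns={
            "SNP": "snp",
            "CHR": "chrom",
            "POS": "pos",
            "REF": "ref",
            "ALT": "alt",
            "Method": "method",
        }
    )


def per_model_loci() -> dict[str, pd.DataFrame]:
    """Reconstruct the per-model significant-locus lists from the bundled table.

    Returns one single-method DataFrame per association model (MLM,
    FarmCPU, BLINK), as each model's scan would have emitted them.
    """
    df = load_published_loci()
    models: dict[str, list] = {}
    for _, row in df.iterrows():
        for method in str(row["method"]).split(","):
            method = method.strip()
            models.setdefault(method, []).append(
                {"snp": row["snp"], "method": method}
            )
    return {m: pd.DataFrame(rows) for m, rows in models.items()}
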