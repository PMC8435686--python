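"""Small reference datasets bundled with the package.

``load_class_richness_reference`` returns the published class-level
compound-richness summary from a comparative fruit-leaf metabolomics
survey of 12 *Piper* species: for each ClassyFire-style chemical class,
the number of spectra-bearing compounds detected in total, the number
unique to fruit organs (seed, unripe or ripe pulp) and the number unique
to leaves.  It is used in examples and as a consistency check on the
organ-partition accounting (the per-class columns must sum to the totals
over classes).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_class_richness_reference", "class_richness_totals"]


def load_class_richness_reference() -> pd.DataFrame:
    """Class-level compound richness (rows: chemical classes; columns:
    total, fruit-specific and leaf-specific richness)."""
    ref = resources.files("phytodiv.data") / "class_richness_reference.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def class_richness_totals() -> dict[str, int]:
    """Column sums over chemical classes (the table's implied Total row)."""
    df = load_class_richness_reference()
    return {
        "total_richness": int(df["total_richness"].sum()),
        "fruit_specific_richness": int(df["fruit_specific_richness"].sum()),
        "leaf_specific_richness": int(df["leaf_specific_richness"].sum()),
    }
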