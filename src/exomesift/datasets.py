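"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_known_indels"]


def load_known_indels() -> pd.DataFrame:
    """The bundled table of known diagnostic indel variants.

    24 deletion/insertion variants from a hereditary-cancer validation
    cohort, each with its transcript, cDNA and protein HGVS names, its
    insertion/deletion class (``I``, ``D`` or ``D/I``) and the number of
    affected reference bases.  Used as a regression panel for the cDNA
    indel parser.
    """
    ref = resources.files("exomesift.data") / "known_indels.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str).assign(
            affected_bases=lambda df: df["affected_bases"].astype(int)
        )
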