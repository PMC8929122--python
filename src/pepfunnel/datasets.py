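"""Bundled desk-scale datasets.

Two small fixtures ship with the package, both transcribed from a published
screen of an in vitro-digested pinto bean protein extract:

* the 37-entry known-bioactive-peptide reference
  (:func:`pepfunnel.reference.bundled_reference`);
* the 15-peptide screening pool that survived the binding filter, with each
  peptide's active-site binding p-value and a flag marking peptides already
  reported as DPP-IV inhibitors.

The union of the two sequence sets (41 unique peptides) serves as the
canonical demo pool.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .peptides import PeptideRecord
from .reference import bundled_reference

__all__ = [
    "bundled_screening_pool",
    "bundled_screening_table",
    "canonical_pool",
]


def _screening_path():
    return resources.files("pepfunnel.data") / "screening_candidates.tsv"


def bundled_screening_table() -> pd.DataFrame:
    """The screening fixture as a DataFrame.

    Columns: ``sequence``, ``binding_pvalue``, ``known_dppiv_inhibitor``
    (yes/no).  15 rows, ordered by ascending p-value.
    """
    with resources.as_file(_screening_path()) as path:
        return pd.read_csv(path, sep="\t")


def bundled_screening_pool() -> list[PeptideRecord]:
    """The 15 binding-filter survivors as pool records.

    Rank scores are absent (the pool is pre-screened upstream); binding
    p-values are attached.
    """
    df = bundled_screening_table()
    return [
        PeptideRecord(sequence=row.sequence,
                      binding_pvalue=float(row.binding_pvalue))
        for row in df.itertuples(index=False)
    ]


def canonical_pool() -> list[PeptideRecord]:
    """Union of reference and screening sequences: 41 unique peptides."""
    pvals = {
        r.sequence: r.binding_pvalue for r in bundled_screening_pool()
    }
    sequences = {e.sequence for e in bundled_reference()} | set(pvals)
    return [
        PeptideRecord(sequence=s, binding_pvalue=pvals.get(s))
        for s in sorted(sequences)
    ]
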