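"""Bundled reference dataset: ApNPV-infection midgut DE measurements.

Two small tables from the published A. pernyi midgut RNA-seq comparison
(2 control vs 2 ApNPV-infected libraries mapped against the A. yamamai
genome) ship with the package:

* ``load_midgut_dels`` -- the 12 differentially expressed LTR elements
  (DELs) with per-group mean FPKM, log2 fold change and FDR;
* ``load_midgut_del_deg_pairs`` -- the 23 neighboring differentially
  expressed genes (DEGs) of those DELs, i.e. the cis pairs entering the
  signed DEL-DEG network, with the DEG log2 fold changes.

They serve as worked-example input and as a fixed ground truth for the
fold-change arithmetic and network-construction stages.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("ltr_cisnet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False, na_values=[])


def load_midgut_dels() -> pd.DataFrame:
    """12 DELs: del_id, ck_mean_fpkm, npv_mean_fpkm, log2fc, fdr."""
    return _read("ap_midgut_dels.tsv")


def load_midgut_del_deg_pairs() -> pd.DataFrame:
    """23 DEL-DEG cis pairs: del_id, gene_id, gene_name, deg_log2fc."""
    return _read("ap_midgut_del_deg_pairs.tsv")
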