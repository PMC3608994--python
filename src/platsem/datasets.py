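"""Packaged example data.

The one shipped fixture is the published Pearson correlation matrix among
four measurement platforms (Sanger sequencing, 454 pyrosequencing of the
V1V3 and V3V5 windows, and qPCR) for the logit-transformed relative
frequency of *Faecalibacterium* in N = 142 subjects of an IBD study.  A
correlation matrix plus N is a sufficient input for every fitting operation
in this package, which is what makes the published table a complete worked
example.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .model_core import MomentSummary

FAECALIBACTERIUM_N = 142


def faecalibacterium_correlations() -> MomentSummary:
    """Four-platform correlation matrix (N = 142) from the IBD study."""
    with resources.files(__package__).joinpath(
            "data/faecalibacterium_correlations.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return MomentSummary(S=df.to_numpy(dtype=float), N=FAECALIBACTERIUM_N,
                         names=list(df.columns), is_correlation=True)


def faecalibacterium_triple(platforms=("Sanger", "454_V3V5", "qPCR")
                            ) -> MomentSummary:
    """A three-platform submatrix of the fixture (default drops 454_V1V3)."""
    return faecalibacterium_correlations().submatrix(list(platforms))
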