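"""Published reference values for summary-table arithmetic checks.

``annual_rsei_reference()`` returns the yearly PC1 eigenvector loadings,
PC1 contribution rate (%) and mean RSEI for a published 21-year
(2000--2020) growing-season Landsat RSEI analysis of a plateau study
region.  The table is used as a fixed input for regression-testing the
annual-summary arithmetic (column means, extrema), not as something the
package recomputes from imagery.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def annual_rsei_reference() -> pd.DataFrame:
    """Yearly reference table: year, four loadings, contribution %, mean RSEI."""
    with resources.files("rseitools.data").joinpath(
            "annual_rsei_reference.csv").open("r") as fh:
        return pd.read_csv(fh)
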