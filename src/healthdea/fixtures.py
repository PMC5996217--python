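"""Bundled example datasets from published extended cost-effectiveness analyses.

Values are stored exactly as printed in the source league tables; no
re-derivation. Monetary columns published in thousands carry their scale as
table metadata — DEA scores are scale-invariant, so the scale matters only
when ICERs are displayed in absolute dollars.

Available fixtures:

``ethiopia_surgery``
    Six policy combinations (universal public finance, task-shifting,
    vouchers) to expand access to surgery in rural Ethiopia; cost input,
    deaths averted and impoverishment averted outcomes (three negative
    impoverishment cells).
``ethiopia_interventions``
    Nine unrelated preventive and curative interventions in Ethiopia;
    government expenditure input (US$ x 1000), household expenditure
    averted (US$ x 1000), deaths averted and impoverishment averted
    outcomes, all nonnegative.
``uganda_cancer``
    Nine government and nongovernmental platforms for surgical cancer care
    in Uganda; cost input and four outcomes including an equity score
    (seven negative cells across impoverishment, catastrophic expense and
    equity).
``box1``
    Three hypothetical policies illustrating the health / financial-risk
    trade-off; the qualitative equity attribute is not quantified and is
    omitted.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .policy_table import PolicyTable

__all__ = ["FIXTURE_NAMES", "load_fixture"]

_SPECS: dict[str, dict] = {
    "ethiopia_surgery": {
        "file": "ethiopia_surgery.csv",
        "input_cols": ["cost"],
        "outcome_cols": ["deaths_averted", "impoverishment_averted"],
        "column_scales": {},
    },
    "ethiopia_interventions": {
        "file": "ethiopia_interventions.csv",
        "input_cols": ["govt_expenditure"],
        "outcome_cols": [
            "household_expenditure_averted",
            "deaths_averted",
            "impoverishment_averted",
        ],
        "column_scales": {
            "govt_expenditure": 1000.0,
            "household_expenditure_averted": 1000.0,
        },
    },
    "uganda_cancer": {
        "file": "uganda_cancer.csv",
        "input_cols": ["cost"],
        "outcome_cols": [
            "deaths_averted",
            "impoverishment_averted",
            "catastrophic_expense_averted",
            "equity_score",
        ],
        "column_scales": {},
    },
    "box1": {
        "file": "box1.csv",
        "input_cols": ["cost"],
        "outcome_cols": ["deaths_averted", "catastrophic_expenditure_averted"],
        "column_scales": {},
    },
}

FIXTURE_NAMES = tuple(_SPECS)


def load_fixture(name: str) -> PolicyTable:
    """Load a bundled dataset by name; see the module docstring for the list."""
    try:
        spec = _SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    with resources.files("healthdea.data").joinpath(spec["file"]).open("r") as fh:
        frame = pd.read_csv(fh)
    return PolicyTable.from_frame(
        frame,
        input_cols=spec["input_cols"],
        outcome_cols=spec["outcome_cols"],
        column_scales=spec["column_scales"],
    )
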