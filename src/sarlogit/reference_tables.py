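"""Published frequency tables of the 2018 Nigerian women's survey.

These counts are the published descriptive margins for the 34,837 women of
reproductive age with complete answers to the five knowledge questions.
They serve as reference inputs: percentages are always recomputed from the
counts by this package, never copied.

Note the newspaper rows total 34,866 although the overall sample is
34,837; proportions are therefore computed within each covariate's own
total (the discrepancy is in the source and is documented, not reproduced).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .outcome import RESPONSE_COLUMNS

#: total respondents with complete knowledge responses
N_WOMEN = 34837

#: "yes" counts per knowledge question, plus the composite outcome
KNOWLEDGE_YES_COUNTS = {
    "heard_hiv": 34836,
    "mtct_pregnancy": 26887,
    "mtct_delivery": 28671,
    "mtct_breastfeeding": 32844,
    "knows_pmtct_drugs": 29699,
}

#: respondents answering yes to all five questions
SUFFICIENT_COUNT = 20611

#: covariate level counts
COVARIATE_COUNTS = {
    "residence": {"urban": 14625, "rural": 20212},
    "marital": {"never_married": 8409, "ever_married": 26427},
    "religion": {"others": 260, "christian": 17879, "islam": 16698},
    "ethnicity": {"others": 13301, "hausa_fulani": 11097, "igbo": 5970, "yoruba": 4469},
    "education": {"none": 11134, "primary": 5289, "secondary": 14417, "higher": 3997},
    "wealth": {
        "poorest": 5914,
        "poorer": 6650,
        "middle": 7433,
        "richer": 7742,
        "richest": 7098,
    },
    "working": {"working": 23104, "not_working": 11733},
    "newspaper": {"yes": 5744, "no": 29122},
    "radio": {"yes": 20058, "no": 14779},
    "television": {"yes": 18338, "no": 16499},
}


def reconstruct_knowledge_records() -> pd.DataFrame:
    """A respondent-level table consistent with the published margins.

    The published margins fix each question's yes count and the number of
    all-yes respondents (the sufficient group), but not the full joint
    distribution among the insufficient. This builds one consistent joint:
    the sufficient block answers yes to everything; among the insufficient,
    each question's remaining yes answers occupy a contiguous cyclic block
    of rows, with offsets chosen so no insufficient row is all-yes.

    Any such joint reproduces every published count exactly, which is all
    the per-question and composite tabulations depend on.
    """
    n_ins = N_WOMEN - SUFFICIENT_COUNT
    data = {c: np.ones(N_WOMEN, dtype=int) for c in RESPONSE_COLUMNS}
    # remaining yes counts among the insufficient rows
    remaining = {
        c: KNOWLEDGE_YES_COUNTS[c] - SUFFICIENT_COUNT for c in RESPONSE_COLUMNS
    }
    offset = 0
    for c in RESPONSE_COLUMNS:
        k = remaining[c]
        col = np.zeros(n_ins, dtype=int)
        idx = (offset + np.arange(k)) % n_ins
        col[idx] = 1
        data[c][SUFFICIENT_COUNT:] = col
        offset += k  # staggered blocks: no insufficient row gets five yeses
    df = pd.DataFrame(data)
    # verify internal consistency before handing the frame out
    for c in RESPONSE_COLUMNS:
        assert int(df[c].sum()) == KNOWLEDGE_YES_COUNTS[c]
    assert int(df.all(axis=1).sum()) == SUFFICIENT_COUNT
    return df
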