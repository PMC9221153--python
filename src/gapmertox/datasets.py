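"""Reference data: the published panel of 13 guanine-free negative-control
gapmers.

These 13 LNA gapmers were designed to have very low acute neurotoxic
potential (no G nucleotides, A count roughly balancing T+C, no perfect and
rare partial complements in the mouse transcriptome).  For each design the
published table reports the base composition, the calculated sequence score
from the trained linear model, and the group-mean acute tolerability score
observed after 100 ug ICV dosing in mice (all below 1, i.e. well
tolerated).
"""

from __future__ import annotations

import pandas as pd

from .gapmer import AsoPanel, parse_gapmer

# (annotated sequence, n_A, n_T, n_C, n_G, calculated score, tolerability)
_NEGATIVE_CONTROLS = [
    ("TCCactaaccaatatAAC", 8, 4, 6, 0, 89, 0.2),
    ("TAActaacttaactcAAC", 8, 5, 5, 0, 89, 0.2),
    ("CACaatctaactattAAC", 8, 5, 5, 0, 89, 0.5),
    ("AAAtctataataaccacCAC", 10, 4, 6, 0, 82, 0.0),
    ("CACaactattaaataccAAC", 10, 4, 6, 0, 82, 0.7),
    ("TACcatacaataactttAAC", 9, 6, 5, 0, 81, 0.0),
    ("CTAatattataaccatcAAC", 9, 6, 5, 0, 81, 0.2),
    ("TACtcaaatataacaccAAC", 10, 4, 6, 0, 82, 0.2),
    ("CAACcaacaatactttAAAC", 10, 4, 6, 0, 82, 0.2),
    ("CAAAtcatccatctatAAAC", 9, 5, 6, 0, 81, 0.0),
    ("CAAActtatatctttcAAAC", 8, 7, 5, 0, 80, 0.0),
    ("CTAAatccttaatatcAAAC", 9, 6, 5, 0, 81, 0.0),
    ("CcAAAtcttataataACtAC", 9, 6, 5, 0, 81, 0.0),
]


def negative_control_panel() -> AsoPanel:
    """The 13 published G-free negative-control gapmers as an
    :class:`~gapmertox.gapmer.AsoPanel`, with the published calculated score
    and mouse tolerability score as annotations."""
    asos = [
        parse_gapmer(seq, id=f"nc{i + 1:02d}")
        for i, (seq, *_rest) in enumerate(_NEGATIVE_CONTROLS)
    ]
    ann = pd.DataFrame(
        {
            "published_calculated_score": [r[5] for r in _NEGATIVE_CONTROLS],
            "tolerability_score": [r[6] for r in _NEGATIVE_CONTROLS],
        },
        index=pd.Index([a.id for a in asos], name="id"),
    )
    return AsoPanel(asos, ann)


def negative_control_table() -> pd.DataFrame:
    """Published composition table for the 13 negative controls: columns
    sequence, n_a, n_t, n_c, n_g, published_calculated_score,
    tolerability_score, indexed by id."""
    return pd.DataFrame(
        _NEGATIVE_CONTROLS,
        columns=[
            "sequence",
            "n_a",
            "n_t",
            "n_c",
            "n_g",
            "published_calculated_score",
            "tolerability_score",
        ],
        index=pd.Index(
            [f"nc{i + 1:02d}" for i in range(len(_NEGATIVE_CONTROLS))],
            name="id",
        ),
    )
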