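"""Bridge expected influence (1-step) across the two communities.

For node i in community C, the 1-step bridge expected influence (BEI) is
the sum of its edge weights to nodes outside C. Both the signed sum (the
textbook definition) and the absolute-value sum are reported: on the
published network the two disagree about the alexithymia bridge node
(signed BEI of EOTS is negative because of its negative edges), and the
reported bridge-node pair is reproducible only under absolute summation,
which is therefore the display default. The per-community argmax of the
chosen variant defines that community's bridge node.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .network import WeightedNetwork

logger = logging.getLogger(__name__)


def bridge_expected_influence(net: WeightedNetwork) -> pd.DataFrame:
    """Per-node signed and absolute 1-step BEI with community labels.

    Raises if the communities do not partition the nodes into >= 2 groups.
    """
    groups = [net.communities[lab] for lab in net.labels]
    if len(set(groups)) < 2:
        raise ValueError("bridge expected influence requires >= 2 "
                         "communities")
    cross = np.array([[groups[i] != groups[j] for j in range(net.p)]
                      for i in range(net.p)])
    w_cross = net.weights * cross
    table = pd.DataFrame({
        "community": groups,
        "bei_signed": w_cross.sum(axis=1),
        "bei_absolute": np.abs(w_cross).sum(axis=1),
    }, index=net.labels)
    table.index.name = "node"
    return table


def identify_bridge_nodes(bridge_table: pd.DataFrame,
                          mode: str = "absolute") -> dict[str, str]:
    """The bridge node (argmax BEI) of each community.

    Ties are broken deterministically by node order, with a logged
    warning — never randomized.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    if bridge_table.empty:
        raise ValueError("empty bridge table")
    col = "bei_signed" if mode == "signed" else "bei_absolute"
    out: dict[str, str] = {}
    for community, sub in bridge_table.groupby("community", sort=False):
        best = sub[col].max()
        winners = sub.index[sub[col] == best]
        if len(winners) > 1:
            logger.warning("BEI tie in community %r between %s; keeping "
                           "first in node order", community, list(winners))
        out[str(community)] = str(winners[0])
    return out
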