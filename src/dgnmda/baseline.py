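"""Logistic-regression reference scorer on raw interaction profiles.

A deliberately simple comparator: the feature vector of a candidate
pair (i, j) is the concatenation of miRNA i's association row and
disease j's association column, both taken from the *training-masked*
matrix so held-out positives contribute no signal.  Any useful graph
encoder should beat this on data whose similarity structure carries
information beyond the raw profiles.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression

from .data import AssociationMatrix
from .protocol import Pair

__all__ = ["logistic_profile_baseline"]


def logistic_profile_baseline(
    assoc_train: AssociationMatrix,
    train_pairs: list[Pair],
    eval_pairs: list[Pair],
    seed: int = 0,
) -> np.ndarray:
    """Fit on train pairs, return probability scores for eval pairs."""

    def feats(pairs):
        return np.array(
            [
                np.concatenate([assoc_train.values[i].astype(float), assoc_train.values[:, j].astype(float)])
                for i, j, _ in pairs
            ]
        )

    x_tr = feats(train_pairs)
    y_tr = np.array([lab for _, _, lab in train_pairs])
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(x_tr, y_tr)
    return clf.predict_proba(feats(eval_pairs))[:, 1]
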