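"""Name -> model-class registry for the four discriminant methods."""

from .linear import DiagonalLDA, VantVeerClassifier
from .boosting import AdaBoost, AUCBoost

METHODS = {
    "vantveer": VantVeerClassifier,
    "dlda": DiagonalLDA,
    "adaboost": AdaBoost,
    "aucboost": AUCBoost,
}

__all__ = ["METHODS"]
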