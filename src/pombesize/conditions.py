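"""Reference parameter sets for seven fission-yeast growth conditions.

These are lineage-data parameter estimates for wild-type fission yeast grown
in Edinburgh minimal medium (EMM, 28-34 degC) and yeast-extract medium
(YE, 28-34 degC), for both the deterministic-partitioning model (model I) and
the beta-partitioning model (model II).  The mean partition ratio ``p`` and
elongation growth rate ``g0`` are common to both models.  ``summary`` holds
the observed mean (sd) of birth size, septation size, division size, lineage
cell size, cell diameter (micrometres) and doubling time (hours) under each
condition, useful as order-of-magnitude checks for synthetic data.

Stage numbers are fractional: the fitting procedure treats Erlang shape
parameters as continuous (gamma) shapes.
"""

from __future__ import annotations

from .params import GrowthParams

__all__ = ["CONDITIONS", "condition_names", "reference_params"]

# condition -> block -> values. "stats" rows are (mean, sd).
CONDITIONS: dict[str, dict] = {
    "EMM_28C": {
        "summary": {"V_b": (7.115, 1.163), "V_s": (13.950, 1.760), "V_d": (15.549, 2.403),
                    "V": (11.159, 2.951), "D": (2.926, 0.282), "T": (4.121, 1.064)},
        "model_I": {"p": 0.459, "alpha": 1.767, "N": 17.463, "N0": 11.262, "N1": 1.214,
                    "a": 0.055, "g0": 0.214, "g1": 0.409},
        "model_II": {"alpha": 2.068, "N": 16.387, "N0": 10.406, "N1": 1.458,
                     "a": 0.025, "nu": 225.97, "g1": 0.376},
    },
    "EMM_30C": {
        "summary": {"V_b": (7.214, 1.096), "V_s": (14.386, 1.694), "V_d": (15.748, 2.100),
                    "V": (11.333, 2.960), "D": (2.977, 0.288), "T": (3.264, 0.667)},
        "model_I": {"p": 0.459, "alpha": 1.695, "N": 20.727, "N0": 13.646, "N1": 0.817,
                    "a": 0.097, "g0": 0.278, "g1": 0.738},
        "model_II": {"alpha": 1.936, "N": 19.051, "N0": 12.250, "N1": 1.124,
                     "a": 0.049, "nu": 257.01, "g1": 0.528},
    },
    "EMM_32C": {
        "summary": {"V_b": (7.604, 1.329), "V_s": (14.341, 1.689), "V_d": (16.289, 2.812),
                    "V": (11.804, 3.158), "D": (2.958, 0.303), "T": (3.107, 0.708)},
        "model_I": {"p": 0.468, "alpha": 1.726, "N": 20.002, "N0": 13.071, "N1": 0.906,
                    "a": 0.085, "g0": 0.280, "g1": 0.767},
        "model_II": {"alpha": 2.068, "N": 18.609, "N0": 11.984, "N1": 1.005,
                     "a": 0.034, "nu": 201.98, "g1": 0.713},
    },
    "EMM_34C": {
        "summary": {"V_b": (7.286, 1.285), "V_s": (14.347, 1.781), "V_d": (15.587, 2.783),
                    "V": (11.364, 3.100), "D": (2.980, 0.292), "T": (3.633, 1.015)},
        "model_I": {"p": 0.470, "alpha": 1.692, "N": 21.010, "N0": 14.623, "N1": 0.714,
                    "a": 0.096, "g0": 0.252, "g1": 0.720},
        "model_II": {"alpha": 1.990, "N": 19.499, "N0": 13.357, "N1": 0.956,
                     "a": 0.043, "nu": 206.33, "g1": 0.558},
    },
    "YE_28C": {
        "summary": {"V_b": (7.066, 1.103), "V_s": (13.480, 1.607), "V_d": (15.189, 2.098),
                    "V": (10.801, 2.931), "D": (2.828, 0.278), "T": (2.651, 0.477)},
        "model_I": {"p": 0.466, "alpha": 1.139, "N": 32.369, "N0": 22.950, "N1": 1.201,
                    "a": 0.755, "g0": 0.328, "g1": 0.618},
        "model_II": {"alpha": 1.419, "N": 30.137, "N0": 21.156, "N1": 2.170,
                     "a": 0.367, "nu": 198.97, "g1": 0.438},
    },
    "YE_30C": {
        "summary": {"V_b": (7.512, 1.036), "V_s": (14.164, 1.649), "V_d": (16.071, 1.971),
                    "V": (11.596, 2.986), "D": (2.981, 0.291), "T": (2.225, 0.435)},
        "model_I": {"p": 0.468, "alpha": 1.371, "N": 45.713, "N0": 29.759, "N1": 1.870,
                    "a": 0.682, "g0": 0.396, "g1": 1.240},
        "model_II": {"alpha": 1.622, "N": 43.905, "N0": 28.099, "N1": 3.161,
                     "a": 0.357, "nu": 272.09, "g1": 0.796},
    },
    "YE_34C": {
        "summary": {"V_b": (7.791, 1.155), "V_s": (14.499, 1.586), "V_d": (16.458, 2.284),
                    "V": (12.078, 3.169), "D": (3.051, 0.318), "T": (1.906, 0.376)},
        "model_I": {"p": 0.475, "alpha": 1.245, "N": 55.315, "N0": 35.092, "N1": 1.864,
                    "a": 1.258, "g0": 0.468, "g1": 1.674},
        "model_II": {"alpha": 1.518, "N": 50.067, "N0": 30.741, "N1": 3.405,
                     "a": 0.574, "nu": 270.18, "g1": 0.931},
    },
}


def condition_names() -> list[str]:
    return list(CONDITIONS)


def reference_params(condition: str, model: str = "I") -> GrowthParams:
    """Fitted :class:`GrowthParams` for a growth condition.

    ``model`` is ``"I"`` (deterministic partitioning, ``nu=None``) or ``"II"``
    (beta partitioning).  For model II, ``p`` and ``g0`` are shared with the
    model I block.
    """
    cond = CONDITIONS[condition]
    m1 = cond["model_I"]
    if model.upper() == "I":
        return GrowthParams(g0=m1["g0"], g1=m1["g1"], a=m1["a"], alpha=m1["alpha"],
                            N=m1["N"], N0=m1["N0"], N1=m1["N1"], p=m1["p"], nu=None)
    if model.upper() == "II":
        m2 = cond["model_II"]
        return GrowthParams(g0=m1["g0"], g1=m2["g1"], a=m2["a"], alpha=m2["alpha"],
                            N=m2["N"], N0=m2["N0"], N1=m2["N1"], p=m1["p"], nu=m2["nu"])
    raise ValueError(f"model must be 'I' or 'II', got {model!r}")
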