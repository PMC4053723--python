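"""Quantitative model linking skewed X inactivation, Xi expression and allelic imbalance.

X-chromosome inactivation (XCI) silences one X in each female cell. In a
female whose cell population is *skewed* -- a fraction ``s`` of cells carry
the same X as the inactive X (Xi) -- a gene expressed from the active X (Xa)
at level 1 and from the Xi at a relative level ``e`` ("%Xi", Xa fixed at 1)
shows a bulk allele-1 expression fraction

    f(s, e) = (s + e * (1 - s)) / (1 + e)

and an allelic imbalance AI = |f - 0.5|.  AI is 0 for balanced bi-allelic
expression and 0.5 for mono-allelic expression.  These three quantities are
the whole quantitative core of the pipeline: skew is estimated from genes
known to be silenced on the Xi (e = 0, where AI = s - 0.5), and observed AI
is inverted to %Xi per gene per female.

Identifiability: the absolute value folds ``e`` and ``1/e`` onto the same AI
(``f(s, e) + f(s, 1/e) = 1``), so inversion from AI alone always returns the
root with ``e <= 1`` -- Xi expression above the Xa level cannot be
distinguished from its reciprocal.  Likewise at ``s = 0.5`` (random XCI) the
AI is 0 for every ``e``: such females carry no information about XCI status,
which is why they are excluded from status calling.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = [
    "CallLevel",
    "GenicStatus",
    "VariableSubtype",
    "ExpressionClass",
    "SkewUnidentifiableError",
    "expected_ai",
    "xi_from_ai",
    "skew_from_subject_ai",
]


class CallLevel(str, enum.Enum):
    """Per-female, per-gene XCI call: three graded escape levels and subject.

    E1 denotes the highest expression from the Xi (AI closest to balance);
    S (subject) denotes less than 10% Xi expression relative to the Xa.
    """

    E1 = "E1"
    E2 = "E2"
    E3 = "E3"
    S = "S"

    @property
    def escapes(self) -> bool:
        return self is not CallLevel.S


class GenicStatus(str, enum.Enum):
    """Per-gene aggregate status across informative females."""

    SUBJECT = "subject"
    VARIABLE_ESCAPE = "variable_escape"
    ESCAPE = "escape"


class VariableSubtype(str, enum.Enum):
    """Subtypes of variable escape.

    bimodal: females are either strongly escaping (E1) or subject;
    borderline: Xi expression hovers near the 10% cutoff (all calls S or E3);
    heterogeneous: a broad continuum of Xi expression levels.
    """

    BIMODAL = "bimodal"
    BORDERLINE = "borderline"
    HETEROGENEOUS = "heterogeneous"


class ExpressionClass(str, enum.Enum):
    """Expression-level classes used for the histone ChIP-AI comparison."""

    ESCAPE_IN_PAR1_RANGE = "escape_in_PAR1_range"
    ESCAPE_OUTSIDE_PAR1_RANGE = "escape_outside_PAR1_range"
    SUBJECT_GE5 = "subject_ge5"
    SUBJECT_LT5 = "subject_lt5"


class SkewUnidentifiableError(ValueError):
    """Raised when AI cannot be inverted to %Xi because skew <= 0.5."""


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def expected_ai(skew, xi):
    """Forward model: AI expected at skew ``s`` and Xi/Xa expression ratio ``e``.

    Parameters
    ----------
    skew : float or array-like in [0.5, 1]
        Fraction of cells with the majority X inactive.
    xi : float or array-like >= 0
        Xi expression as a ratio of Xa expression (1 = Xi expresses at the
        Xa level).

    Returns
    -------
    AI in [0, 0.5]; symmetric in the choice of major allele.
    """
    s, s_scalar = _as_array(skew)
    e, e_scalar = _as_array(xi)
    if np.any(s < 0.5) or np.any(s > 1.0):
        raise ValueError(f"skew must lie in [0.5, 1], got {skew!r}")
    if np.any(e < 0):
        raise ValueError(f"xi must be >= 0, got {xi!r}")
    f = (s + e * (1.0 - s)) / (1.0 + e)
    ai = np.abs(f - 0.5)
    return float(ai) if (s_scalar and e_scalar) else ai


def xi_from_ai(ai, skew):
    """Invert the forward model: %Xi implied by an observed AI at a given skew.

    Solves ``f = (s + e(1-s)) / (1+e)`` for ``e`` with ``f = 0.5 + ai`` (the
    major-allele fraction), giving ``e = (f - s) / (1 - s - f)``.  Negative
    solutions -- AI larger than the fully-silenced expectation ``s - 0.5``,
    typically from underestimated skew -- are clamped to 0 so downstream
    consumers never see a negative %Xi.

    Raises
    ------
    SkewUnidentifiableError
        If ``skew <= 0.5``: at random XCI every %Xi yields AI 0, so the
        inversion is undefined (only group 1/2 females may be converted).
    """
    a, a_scalar = _as_array(ai)
    s, s_scalar = _as_array(skew)
    if np.any(a < 0) or np.any(a > 0.5):
        raise ValueError(f"AI must lie in [0, 0.5], got {ai!r}")
    if np.any(s <= 0.5) or np.any(s > 1.0):
        raise SkewUnidentifiableError(
            f"%Xi is only identifiable for skew > 0.5, got {skew!r}"
        )
    f = 0.5 + a
    with np.errstate(divide="ignore"):
        e = (f - s) / (1.0 - s - f)
    e = np.clip(e, 0.0, None)
    return float(e) if (a_scalar and s_scalar) else e


def skew_from_subject_ai(avg_subject_ai):
    """Skew fraction implied by the mean AI of fully Xi-silenced genes.

    At ``e = 0`` the forward model reduces to ``AI = s - 0.5``, so the mean
    genic AI over a set of genes known to be subject to XCI estimates the
    skewing of the female as ``0.5 + AI``.
    """
    a, scalar = _as_array(avg_subject_ai)
    if np.any(a < 0) or np.any(a > 0.5):
        raise ValueError(f"average subject AI must lie in [0, 0.5], got {avg_subject_ai!r}")
    s = 0.5 + a
    return float(s) if scalar else s
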