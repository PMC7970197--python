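"""Controlled vocabularies for speech annotation.

Two annotation schemes are supported:

* a 14-label speech tag set designed around the roles gaze plays in social
  communication (questions, pauses by duration class, laughter, thinking
  fillers, ...);
* ISO 24617-2 dialogue acts (9 dimensions, 56 communicative functions) with
  ISO 24617-8 DR-Core rhetorical relations (18 labels).
"""

from __future__ import annotations

from enum import Enum


class SpeechTag(str, Enum):
    """The 14-label speech tag set.

    ``MICRO_PAUSE`` covers gaps up to 200 ms; ``SPEECH_PAUSE`` covers pauses
    not classed as micro pauses or pre-speech warm-up.
    """

    SPEECH = "Speech"
    ASKING_A_QUESTION = "Asking a Question"
    CONFIRMATION = "Confirmation"
    PRE_SPEECH = "Pre-Speech"
    SPEECH_PAUSE = "Speech Pause"
    MICRO_PAUSE = "Micro Pause"
    SIGNALING_END_OF_SPEECH = "Signaling End of Speech"
    THINKING = "Thinking"
    READ_QUESTION = "Read Question"
    REPETITION_OF_THE_QUESTION = "Repetition of the Question"
    LAUGH = "Laugh"
    SPEECH_WHILE_LAUGHING = "Speech While Laughing"
    GREETING = "Greeting"
    QUESTIONNAIRE_FILLING = "Questionnaire Filling"


SPEECH_TAGS: tuple[str, ...] = tuple(t.value for t in SpeechTag)

#: Upper duration bound for a Micro Pause, ms.
MICRO_PAUSE_MAX_MS: float = 200.0


# --- ISO 24617-2 ----------------------------------------------------------

#: The nine dimensions (semantic-content categories) of ISO 24617-2.
DIMENSIONS: tuple[str, ...] = (
    "Task",
    "Auto-feedback",
    "Allo-feedback",
    "Turn management",
    "Time management",
    "Own communication management",
    "Partner communication management",
    "Discourse structuring",
    "Social obligations management",
)

#: General-purpose communicative functions: admissible in every dimension.
GENERAL_PURPOSE_FUNCTIONS: tuple[str, ...] = (
    "Inform",
    "Agreement",
    "Disagreement",
    "Correction",
    "Answer",
    "Confirm",
    "Disconfirm",
    "Question",
    "PropositionalQuestion",
    "SetQuestion",
    "ChoiceQuestion",
    "CheckQuestion",
    "Offer",
    "AddressOffer",
    "AcceptOffer",
    "DeclineOffer",
    "Request",
    "AddressRequest",
    "AcceptRequest",
    "DeclineRequest",
    "Suggestion",
    "AddressSuggestion",
    "AcceptSuggestion",
    "DeclineSuggestion",
    "Instruct",
    "Promise",
)

#: Dimension-specific communicative functions, keyed by their only legal
#: dimension.  General-purpose functions are additionally legal everywhere.
DIMENSION_SPECIFIC_FUNCTIONS: dict[str, tuple[str, ...]] = {
    "Task": (),
    "Auto-feedback": ("AutoPositive", "AutoNegative"),
    "Allo-feedback": ("AlloPositive", "AlloNegative", "FeedbackElicitation"),
    "Turn management": (
        "TurnAccept",
        "TurnAssign",
        "TurnGrab",
        "TurnKeep",
        "TurnRelease",
        "TurnTake",
    ),
    "Time management": ("Stalling", "Pausing"),
    "Own communication management": ("SelfCorrection", "SelfError", "Retraction"),
    "Partner communication management": ("Completion", "CorrectMisspeaking"),
    "Discourse structuring": ("InteractionStructuring", "Opening"),
    "Social obligations management": (
        "InitialGreeting",
        "ReturnGreeting",
        "InitialSelfIntroduction",
        "ReturnSelfIntroduction",
        "Apology",
        "AcceptApology",
        "Thanking",
        "AcceptThanking",
        "InitialGoodbye",
        "ReturnGoodbye",
    ),
}

#: All 56 communicative functions of the standard, general-purpose first.
COMMUNICATIVE_FUNCTIONS: tuple[str, ...] = GENERAL_PURPOSE_FUNCTIONS + tuple(
    f for funcs in DIMENSION_SPECIFIC_FUNCTIONS.values() for f in funcs
)

#: Functions not encountered in the interview corpus this package models;
#: they stay in the vocabulary but are flagged for linting.
UNSEEN_IN_CORPUS: frozenset[str] = frozenset(
    {
        "Correction",
        "AcceptOffer",
        "DeclineOffer",
        "DeclineRequest",
        "DeclineSuggestion",
        "AutoNegative",
        "AlloNegative",
        "FeedbackElicitation",
        "ReturnSelfIntroduction",
        "Question",
        "AddressOffer",
        "AddressRequest",
        "AddressSuggestion",
    }
)

#: Home dimension of each dimension-specific function.
_FUNCTION_DIMENSION: dict[str, str] = {
    f: dim for dim, funcs in DIMENSION_SPECIFIC_FUNCTIONS.items() for f in funcs
}


def function_allowed_in(function: str, dimension: str) -> bool:
    """Whether ``function`` may be annotated under ``dimension``.

    General-purpose functions are legal in every dimension; a
    dimension-specific function only in its home dimension.
    """
    if function in GENERAL_PURPOSE_FUNCTIONS:
        return True
    home = _FUNCTION_DIMENSION.get(function)
    return home == dimension


# --- ISO 24617-8 (DR-Core) ------------------------------------------------

#: The 18 rhetorical-relation labels of the DR-Core annotation schema.
RHETORICAL_RELATIONS: tuple[str, ...] = (
    "Cause",
    "Condition",
    "NegativeCondition",
    "Purpose",
    "Manner",
    "Concession",
    "Contrast",
    "Exception",
    "Similarity",
    "Substitution",
    "Conjunction",
    "Disjunction",
    "Exemplification",
    "Elaboration",
    "Expansion",
    "Restatement",
    "Synchrony",
    "Asynchrony",
)

#: Qualifier vocabularies (``""`` = unqualified).
CERTAINTY_VALUES: tuple[str, ...] = ("", "Certain", "Uncertain", "Conditional")
SENTIMENT_VALUES: tuple[str, ...] = ("", "Positive", "Negative", "Neutral")
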