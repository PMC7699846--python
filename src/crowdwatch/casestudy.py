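"""Worked example: the ten topics reported around the 2014 Shanghai
New Year's Eve stampede.

Topic summaries extracted from Bund-area posts on the night of the stampede
fall into four classes: complaints about the huge crowd, relief at having
stayed away, blessings for the victims, and unrelated chatter. Each entry
below carries the topic's class key words (multi-word key phrases kept as
single atomic tokens) together with neutral gloss words; the keyword
classification rule in :mod:`crowdwatch.topics` recovers the class
memberships from these word lists alone.

Topics are numbered 1..10 as in the source case study of this event.
"""

from __future__ import annotations

from .topics import TopicClassMap

#: Per-class key words for the Shanghai case (atomic tokens; phrases intact).
SHANGHAI_CLASS_MAP = TopicClassMap(
    keywords={
        "crowd_complaint": frozenset({"huge crowd", "bund", "death"}),
        "relief": frozenset({"stampede", "gloat", "being alive"}),
        "blessing": frozenset(
            {"rest in peace", "pray for the deceased and injured"}
        ),
    },
    top_k=10,
)

#: topic number -> most frequent words (class key words + gloss words).
SHANGHAI_TOPIC_WORDS: dict[int, tuple[str, ...]] = {
    1: ("stampede", "fortunate", "missed", "yesterday", "gloat", "being alive"),
    2: ("hello", "shanghai", "bund", "huge crowd", "people", "walking"),
    3: ("fun", "many people", "huge crowd", "together"),
    4: ("good morning", "good luck", "blessed", "family", "gloat", "being alive"),
    5: ("happy", "cold wave", "weather", "feel"),
    6: ("happy days", "breakfast", "nice", "morning"),
    7: ("working hard", "early morning", "start", "rest in peace"),
    8: ("sharing", "songs", "dead", "memorial"),
    9: ("many people", "died", "tonight", "stay calm", "mass gathering", "death"),
    10: (
        "hoping",
        "dead",
        "rest in peace",
        "pray for the deceased and injured",
    ),
}


def classify_case_topics() -> dict[int, str]:
    """Apply the keyword rule to the ten case-study topic word lists."""
    from .topics import classify_keywords

    return {
        num: classify_keywords(words, SHANGHAI_CLASS_MAP)
        for num, words in SHANGHAI_TOPIC_WORDS.items()
    }
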