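"""Reference instrument structure and published summary statistics.

The final LAM health-related-quality-of-life questionnaire that motivates
this package has 32 items: four rescaled domains — Exertional dyspnea
(13 items), Cough (6), Fatigue (5), Emotional well-being (5) — plus three
standalone items that contribute only to the total score.  Summation
scoring gives each k-item scale the possible range [k, 6k].

``OXYGEN_GROUP_STATS`` holds the per-scale score summaries reported in the
instrument's original development study for respondents using versus not
using supplemental oxygen; they serve as inputs for recomputing derived
columns (differences, pooled sds, effect sizes) at summary level.
"""

from __future__ import annotations

from .core import InstrumentDefinition, ItemDef

FINAL_DOMAIN_SIZES = {
    "exertional_dyspnea": 13,
    "cough": 6,
    "fatigue": 5,
    "emotional": 5,
}
N_STANDALONE = 3

_ANCHORS = {
    "exertional_dyspnea": ("I am never short of breath with activity",
                           "I am always short of breath with activity"),
    "cough": ("My cough does not bother me at all",
              "My cough bothers me constantly"),
    "fatigue": ("I have plenty of energy",
                "I am exhausted all the time"),
    "emotional": ("I feel calm about my illness",
                  "I feel overwhelmed by my illness"),
    None: ("My lung disease does not limit my life",
           "My lung disease dominates my life"),
}

_PREFIX = {"exertional_dyspnea": "dysp", "cough": "cough",
           "fatigue": "fat", "emotional": "emot"}


def final_instrument() -> InstrumentDefinition:
    """The final 32-item, four-domain instrument structure."""
    items = []
    for domain, k in FINAL_DOMAIN_SIZES.items():
        left, right = _ANCHORS[domain]
        for i in range(k):
            items.append(ItemDef(f"{_PREFIX[domain]}{i+1:02d}",
                                 left, right, domain))
    left, right = _ANCHORS[None]
    for i in range(N_STANDALONE):
        items.append(ItemDef(f"glob{i+1:02d}", left, right, None))
    return InstrumentDefinition(items=items,
                                domains=list(FINAL_DOMAIN_SIZES))


#: per-scale (mean, sd, n) for the oxygen-ever and oxygen-never groups,
#: as reported in the original development study (n = 29 vs 35)
OXYGEN_GROUP_STATS = {
    "exertional_dyspnea": {"ever": (43.1, 14.0, 29), "never": (27.7, 12.5, 35)},
    "cough":              {"ever": (15.6, 6.7, 29),  "never": (12.5, 7.1, 35)},
    "fatigue":            {"ever": (19.2, 7.2, 29),  "never": (12.7, 5.6, 35)},
    "emotional":          {"ever": (17.1, 8.5, 29),  "never": (12.3, 5.6, 35)},
    "total":              {"ever": (104.1, 34.1, 29), "never": (71.3, 27.3, 35)},
}
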