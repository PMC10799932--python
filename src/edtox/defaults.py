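"""Packaged default configuration: code spec, lexicon, keywords, lab panel.

All of these are plain data and can be overridden by user-supplied YAML/JSON
config files (see :mod:`edtox.ehr_io`).  The lexicon ships with English
surfaces; sites using another language supply their own lexicon with the
same wildcard/variant conventions.
"""

from __future__ import annotations

#: Reason-for-attending keywords scanned against the triage/referral text.
#: Multi-word keywords match as contiguous token phrases.
DEFAULT_REASON_KEYWORDS: tuple[str, ...] = (
    "intoxication",
    "intoxicant",
    "impaired consciousness",
    "unconsciousness",
    "convulsion",
    "drug",
    "substance abuse",
)

#: ICD-10 code specification for the diagnosis arm.  Single categories,
#: "#"-marked categories (any subcode; a display convention — every category
#: matches any of its subcodes) and inclusive three-character ranges.
#: Expands to 43 categories.
DEFAULT_CODE_SPEC: tuple[str, ...] = (
    "F10",        # alcohol-related mental & behavioural disorder
    "F11-F16",    # drug-related mental & behavioural disorders
    "F19",
    "X00-X09",    # smoke/fire exposure
    "X44-X49",    # accidental poisoning
    "X69",        # intentional self-poisoning
    "T36#",       # poisoning by systemic antibiotics (any subcode)
    "T40",        # poisoning by narcotics/psychodysleptics
    "T50",        # poisoning, other/unspecified drugs
    "T51-T65",    # toxic effects of substances
)

#: Free-word-search lexicon: 20 concepts.  A trailing "*" marks a prefix
#: wildcard (stem search); entries may carry literal variant forms standing
#: in for inflections or synonyms.
DEFAULT_LEXICON_ENTRIES: tuple[object, ...] = (
    "Intox*",
    "Overdose",
    "Convuls*",
    "Unconscious*",
    "Poison",
    "Drug",
    "Drunk",
    "Alcohol",
    "Per mille",
    "Substance",
    "Blood test for poison",
    "Self-harm",
    "Benzodiazepin*",
    {"surface": "Amphetamine", "variants": ["methamphetamine", "mdma"]},
    "Gamma",
    "Cocain*",
    "Cannabi*",
    {"surface": "Opiates", "variants": ["opioid", "opioids"]},
    "Hypoglycem*",
    "Fire",
)

#: Substance classes recognised system-wide.
SUBSTANCE_CLASSES: tuple[str, ...] = (
    "ethanol",
    "benzodiazepines",
    "other_pharmaceuticals",
    "cannabinoids",
    "amphetamines",
    "opioids",
    "cocaine",
    "other",
)

#: Default laboratory panel for the lab arm.  `kind` is "quantitative" or
#: "qualitative"; quantitative analytes hit when value exceeds `threshold`
#: (exclusive), qualitative ones when flagged positive.
DEFAULT_LAB_PANEL: dict[str, dict] = {
    "ethanol_blood": {
        "unit": "mmol_per_L", "kind": "quantitative", "threshold": 0.0,
        "substance_class": "ethanol",
    },
    "ethanol_breath": {
        "unit": "per_mille", "kind": "quantitative", "threshold": 0.0,
        "substance_class": "ethanol",
    },
    "amphetamines_urine": {
        "unit": "qualitative_pos_neg", "kind": "qualitative",
        "substance_class": "amphetamines",
    },
    "benzodiazepines_urine": {
        "unit": "qualitative_pos_neg", "kind": "qualitative",
        "substance_class": "benzodiazepines",
    },
    "cannabinoids_urine": {
        "unit": "qualitative_pos_neg", "kind": "qualitative",
        "substance_class": "cannabinoids",
    },
    "opioids_urine": {
        "unit": "qualitative_pos_neg", "kind": "qualitative",
        "substance_class": "opioids",
    },
    "cocaine_urine": {
        "unit": "qualitative_pos_neg", "kind": "qualitative",
        "substance_class": "cocaine",
    },
    "paracetamol_serum": {
        "unit": "mg_per_L", "kind": "quantitative", "threshold": 0.0,
        "substance_class": "other_pharmaceuticals",
    },
    "antidepressants_screen": {
        "unit": "qualitative_pos_neg", "kind": "qualitative",
        "substance_class": "other_pharmaceuticals",
    },
}

#: Qualitative urine screen for each screenable non-ethanol class.
SCREEN_FOR_CLASS: dict[str, str] = {
    "amphetamines": "amphetamines_urine",
    "benzodiazepines": "benzodiazepines_urine",
    "cannabinoids": "cannabinoids_urine",
    "opioids": "opioids_urine",
    "cocaine": "cocaine_urine",
    "other_pharmaceuticals": "antidepressants_screen",
}

#: Default toxicity ordering, most significant first.  Ethanol splits into a
#: BAC-dependent pair so that at least moderate alcohol intoxication outranks
#: incidental cannabinoid positivity while trace alcohol ranks last.
DEFAULT_TOXICITY_ORDER: tuple[str, ...] = (
    "other",                  # envenomation, carbon monoxide, plant toxins
    "opioids",
    "other_pharmaceuticals",
    "amphetamines",
    "cocaine",
    "benzodiazepines",
    "ethanol_high",           # BAC at or above the moderate threshold
    "cannabinoids",
    "ethanol_low",
)
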