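{
  "description": "Item catalog for the three questionnaires pooled into the composite-index item bank: EQ-5D-5L (5 items, levels 1-5), ODI (10 items, 0-5) and HADS (14 items, 0-3, reverse-keyed items assumed already re-coded so that higher = worse).",
  "items": [
    {"item_id": "EQ5D_Mobility", "instrument": "EQ5D", "position": 1, "min": 1, "max": 5, "subscale": null, "label": "Mobility"},
    {"item_id": "EQ5D_SelfCare", "instrument": "EQ5D", "position": 2, "min": 1, "max": 5, "subscale": null, "label": "Self care"},
    {"item_id": "EQ5D_UsualActivities", "instrument": "EQ5D", "position": 3, "min": 1, "max": 5, "subscale": null, "label": "Usual activities"},
    {"item_id": "EQ5D_AnxietyDepression", "instrument": "EQ5D", "position": 4, "min": 1, "max": 5, "subscale": null, "label": "Anxiety/Depression"},
    {"item_id": "EQ5D_PainDiscomfort", "instrument": "EQ5D", "position": 5, "min": 1, "max": 5, "subscale": null, "label": "Pain/Discomfort"},
    {"item_id": "ODI_PainIntensity", "instrument": "ODI", "position": 1, "min": 0, "max": 5, "subscale": null, "label": "Pain intensity"},
    {"item_id": "ODI_PersonalCare", "instrument": "ODI", "position": 2, "min": 0, "max": 5, "subscale": null, "label": "Personal care"},
    {"item_id": "ODI_Lifting", "instrument": "ODI", "position": 3, "min": 0, "max": 5, "subscale": null, "label": "Lifting"},
    {"item_id": "ODI_Walking", "instrument": "ODI", "position": 4, "min": 0, "max": 5, "subscale": null, "label": "Walking"},
    {"item_id": "ODI_Sitting", "instrument": "ODI", "position": 5, "min": 0, "max": 5, "subscale": null, "label": "Sitting"},
    {"item_id": "ODI_Standing", "instrument": "ODI", "position": 6, "min": 0, "max": 5, "subscale": null, "label": "Standing"},
    {"item_id": "ODI_Sleeping", "instrument": "ODI", "position": 7, "min": 0, "max": 5, "subscale": null, "label": "Sleeping"},
    {"item_id": "ODI_SexLife", "instrument": "ODI", "position": 8, "min": 0, "max": 5, "subscale": null, "label": "Sex life"},
    {"item_id": "ODI_SocialLife", "instrument": "ODI", "position": 9, "min": 0, "max": 5, "subscale": null, "label": "Social life"},
    {"item_id": "ODI_Travelling", "instrument": "ODI", "position": 10, "min": 0, "max": 5, "subscale": null, "label": "Travelling"},
    {"item_id": "HAD_Tense", "instrument": "HADS", "position": 1, "min": 0, "max": 3, "subscale": "anxiety", "label": "Feeling tense or 'wound up'"},
    {"item_id": "HAD_Enjoy", "instrument": "HADS", "position": 2, "min": 0, "max": 3, "subscale": "depression", "label": "Enjoying things you used to enjoy"},
    {"item_id": "HAD_Awful", "instrument": "HADS", "position": 3, "min": 0, "max": 3, "subscale": "anxiety", "label": "Feeling that something awful is about to happen"},
    {"item_id": "HAD_Laugh", "instrument": "HADS", "position": 4, "min": 0, "max": 3, "subscale": "depression", "label": "Laughing and seeing the good side of things"},
    {"item_id": "HAD_Worry", "instrument": "HADS", "position": 5, "min": 0, "max": 3, "subscale": "anxiety", "label": "Worrying thoughts going through your mind"},
    {"item_id": "HAD_Cheerful", "instrument": "HADS", "position": 6, "min": 0, "max": 3, "subscale": "depression", "label": "Feeling cheerful"},
    {"item_id": "HAD_Relaxed", "instrument": "HADS", "position": 7, "min": 0, "max": 3, "subscale": "anxiety", "label": "Can sit at ease and feel relaxed"},
    {"item_id": "HAD_SlowedDown", "instrument": "HADS", "position": 8, "min": 0, "max": 3, "subscale": "depression", "label": "Feeling slowed down"},
    {"item_id": "HAD_Butterflies", "instrument": "HADS", "position": 9, "min": 0, "max": 3, "subscale": "anxiety", "label": "Frightened feeling like 'butterflies' in the stomach"},
    {"item_id": "HAD_Appearance", "instrument": "HADS", "position": 10, "min": 0, "max": 3, "subscale": "depression", "label": "Lost interest in appearance"},
    {"item_id": "HAD_Restless", "instrument": "HADS", "position": 11, "min": 0, "max": 3, "subscale": "anxiety", "label": "Feeling restless as if on the move"},
    {"item_id": "HAD_LookForward", "instrument": "HADS", "position": 12, "min": 0, "max": 3, "subscale": "depression", "label": "Looking forward with enjoyment to things"},
    {"item_id": "HAD_Panic", "instrument": "HADS", "position": 13, "min": 0, "max": 3, "subscale": "anxiety", "label": "Sudden feeling of panic"},
    {"item_id": "HAD_Book", "instrument": "HADS", "position": 14, "min": 0, "max": 3, "subscale": "depression", "label": "Enjoying a good book or radio/TV program"}
  ]
}
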