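"""Derive 12-month-confirmed disability events from an EDSS trajectory.

Shows the two cleaning/confirmation rules at work: a score recorded 10
days after a relapse is excluded, and a worsening must be held by every
later score for at least 365 days before it counts.
"""

from msmtrial import EdssScore, clean_edss, detect_confirmed_events

visits = [
    EdssScore(0, 2.0),
    EdssScore(190, 3.5),   # 10 days after the relapse at 180: excluded
    EdssScore(360, 3.0),   # 1-step worsening candidate
    EdssScore(540, 3.0),
    EdssScore(760, 3.0),   # >= 365 d after onset: confirms the event
    EdssScore(950, 2.0),   # 1-step improvement from the new reference
    EdssScore(1340, 2.0),  # confirms the improvement
]
relapses = [180]

cleaned = clean_edss(visits, relapses)
print(f"scores kept after post-relapse exclusion: {len(cleaned)}/{len(visits)}")

for event in detect_confirmed_events(cleaned, reference_policy="roving"):
    print(
        f"{event.kind:11s} onset day {event.onset_day:4d} "
        f"(EDSS {event.reference_edss} -> {event.onset_edss}), "
        f"confirmed day {event.confirmation_day}"
    )
print(
    "The roving reference resets to 3.0 after the confirmed worsening, "
    "so the later drop to 2.0 qualifies as an improvement."
)
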