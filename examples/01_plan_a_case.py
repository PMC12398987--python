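"""Plan a few findings charts with the deterministic rule engine.

Each chart lists one finding per tooth across a 16-tooth jaw; the
planner returns one prosthesis choice per tooth: "-" nothing, "K" crown,
"B" bridge unit, "E" replacement on a removable denture.
"""

from prosthoplan import parse_chart, plan_case_explained

EXAMPLES = [
    # a single missing premolar: bridged, with crowned abutments either side
    ". . . . . . . f . . . . . . . .",
    # four missing teeth cross the standard-care threshold: removable denture
    ". . . . f f f f . . . . . . . .",
    # a worn-out bridge (kw bw kw) is renewed as a whole
    ". . . kw bw kw . . . . . . . . . .",
    # an insufficient denture forces renewal; the new gap joins it
    ". . ew ew . . . . . f . . . . . .",
    # a missing wisdom tooth needs no replacement
    "f . . . . . . . . . . . . . . .",
]

for text in EXAMPLES:
    chart = parse_chart(text, "finding")
    plan, rules = plan_case_explained(chart)
    print(f"findings: {chart}")
    print(f"plan:     {plan}")
    fired = {r for r in rules if r != "P6"}
    print(f"rules:    {', '.join(sorted(fired)) or 'none'}\n")

print("P1 missing wisdom tooth untreated; P2 removable pathway; "
      "P3 new bridge; P4 renewal of fixed work; P5 crown for a "
      "preservation-worthy tooth.")
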