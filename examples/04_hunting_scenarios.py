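"""The predator's hunting rules, replayed one by one.

Each scripted scenario drives the four-stage state machine (search, wait,
hunt, satisfaction) with hand-placed positions and prints the event
stream it produces: target selection, wait-stage escape, hunt time-out,
contact kill with stage skip, predator confusion, and handling time.
"""

from flockhunt.io import generate_scenarios, play_scenario

for sc in generate_scenarios():
    outcome = play_scenario(sc)
    names = " -> ".join(e[0] for e in outcome.events)
    ok = [e[0] for e in outcome.events] == sc.expected_events
    print(f"{sc.name:32s} {names}  [{'ok' if ok else 'MISMATCH'}]")
# every line should end [ok]: the event stream matches the scripted
# expectation for that hunting rule.
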