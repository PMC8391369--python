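"""A scripted therapy session with a synthetic patient.

Builds a seeded profile, opens a session over the shipped Spanish
knowledge base and replays a short conversation.  The printed lines show
how the engine personalizes its responses (the relative's name, the
favourite dish come straight from the profile) and how every turn ends
with a question that invites the patient to keep talking.
"""

from recuerda import DialogueEngine, export_transcript, generate_profile

profile = generate_profile(seed=1)
print(f"patient: {profile.answers['patient_name']}, "
      f"first relative: {profile.family[0].name} ({profile.family[0].relationship})\n")

engine = DialogueEngine()
session, opening = engine.start_session(profile, seed=7)
print(f"  SYSTEM: {opening}")

for line in [
    "hola",
    "quiero platicar de mi familia",
    "sí",
    "no me acuerdo muy bien",
    "vamos a platicar de comida",
    "sí claro",
    "adiós",
]:
    response = engine.step(session, line)
    print(f"  USER:   {line}")
    print(f"  SYSTEM: {response}")
    if session.closed:
        break

summary = engine.end_session(session) if not session.summarized else None
print(f"\nexchanges: {session.turn_index}, contexts visited: {session.contexts_visited}")
print("transcript (JSONL, first line):")
print(" ", export_transcript(session).splitlines()[0])
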