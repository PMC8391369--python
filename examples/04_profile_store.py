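"""Profile lifecycle: questionnaire, storage, derived slots, deletion.

Creates a profile from a handful of questionnaire answers plus a family
list, shows the derived family slots used by customized templates, and
demonstrates the withdrawal contract: deleting a patient removes the
profile document and every session log, verifiably.
"""

import tempfile

from recuerda import DialogueEngine, FamilyMember, ProfileStore, default_schema, export_transcript

schema = default_schema()
print(f"questionnaire: {[len(b.questions) for b in schema.blocks]} questions "
      f"per topic block, {len(schema)} total")

with tempfile.TemporaryDirectory() as tmp:
    store = ProfileStore(tmp)
    profile = store.create_profile(
        schema,
        {"patient_name": "María", "comida_favorita": "el mole poblano"},
        [FamilyMember(1, "Patricia", "hija")],
    )
    print(f"\nstored {profile.patient_id}")
    print(f"  fam1_name        -> {profile.get_slot('fam1_name')}")
    print(f"  parentesco_fam1  -> {profile.get_slot('parentesco_fam1')}")
    print(f"  apodo (missing)  -> {profile.get_slot('apodo')}")

    engine = DialogueEngine()
    session, _ = engine.start_session(profile, seed=1)
    engine.step(session, "hola")
    store.save_session_log(profile.patient_id, session.session_id,
                           export_transcript(session))

    report = store.delete_profile(profile.patient_id)
    print(f"\ndeleted profile: {report.removed_profile}")
    print(f"deleted session logs: {len(report.removed_session_logs)}")
    leftovers = [p for p in store.root.rglob("*") if profile.patient_id in p.name]
    print(f"files still referencing the patient: {len(leftovers)}")
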