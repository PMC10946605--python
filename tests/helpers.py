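"""Handmade-record helpers shared across test modules."""

from msmtrial.registry import EdssScore, PatientRecord, TreatmentEpisode

Y = 365


def make_patient(
    pid="P0",
    sex="female",
    birth=-30 * Y,
    onset=0,
    visits=((0, 2.0), (180, 2.0), (360, 2.0), (540, 2.0), (720, 2.0)),
    relapses=(),
    treatments=(),
    courses=(("RRMS", 0),),
    mri=(),
    pregnancies=(),
):
    """Handmade validated patient; days relative to MS onset at day 0."""
    rec = PatientRecord(
        patient_id=pid,
        sex=sex,
        birth=birth,
        onset=onset,
        course_history=list(courses),
        visits=[EdssScore(d, v) for d, v in visits],
        relapses=list(relapses),
        treatments=[TreatmentEpisode("DMT", s, e) for s, e in treatments],
        mri=list(mri),
        pregnancies=list(pregnancies),
    )
    return rec.validated()
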