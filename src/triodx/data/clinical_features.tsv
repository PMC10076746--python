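sample_id	sex	features
ASD0018	male	Intellectual disability, language development delay
ASD0027	male	Severe intellectual disability, language retardation, wide dental space, abnormal posture
ASD0046	female	Intellectual disability, language retardation, attention deficit, hyperactivity, feeding difficulties
ASD0060	male	Intellectual disability, language development delay, sleep disorders, forehead protrusion
ASD0061	male	Intellectual disability, language development delay, global developmental delay
ASD0063	female	Intellectual disability, language retardation, movement disorders, epilepsy
ASD0134	male	Intellectual disability, language retardation, hyperactivity, strabismus, unsteady walking
ASD0144	male	Intellectual disability, language development delay, learning disabilities, cognitive disorders, attention deficit, feeding difficulties
ASD0148	female	Intellectual disability, language retardation, motor retardation, increased pain tolerance, spherical nasal tip
ASD0162	male	Intellectual disability, language deficits, learning disabilities, large head, scoliosis, multiple milky coffee spots
ASD0203	female	Attention deficit, hyperactivity, global developmental delay
ASD0214	female	Intellectual disability, language deficits, global developmental delay, cognitive disorders, feeding difficulties
ASD0219	female	Mild intellectual disability, language development delay, cognitive disorders, hyperactivity, gross/fine motor retardation
ASD0221	male	Intellectual disability, language absence, motor retardation, instability of gait
ASD0222	female	Mild intellectual disability, language development delay, motor retardation
ASD0294	male	Intellectual disability, language development delay, global development delay
ASD0326	male	Mild intellectual disability, language development delay, global development delay
ASD0330	male	lost of follow-up
ASD0343	male	Intellectual disability, language development delay, cognitive disorders, learning disabilities, hyperactivity
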