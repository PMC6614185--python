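group	member
Proton Pump Inhibitors (PPI)	Omeprazole
Proton Pump Inhibitors (PPI)	Pantoprazole
Proton Pump Inhibitors (PPI)	Lansoprazole
Proton Pump Inhibitors (PPI)	Esomeprazole
SSRI	Citalopram
SSRI	Escitalopram
SSRI	Sertraline
SSRI	Paroxetine
Tricyclic antidepressants	Amitriptyline
Tricyclic antidepressants	Clomipramine
Tricyclic antidepressants	Doxepin
Tricyclic antidepressants	Imipramine
Tricyclic antidepressants	Nortriptyline
Opioids	Codeine
Opioids	Oxycodone
Opioids	Tramadol
Simvastatin and Atorvastatin	Simvastatin
Simvastatin and Atorvastatin	Atorvastatin
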