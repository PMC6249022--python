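signature	aetiology
Signature 1	Spontaneous deamination of 5-methylcytosine
Signature 2	Activity of the AID/APOBEC family of cytidine deaminases
Signature 4	Exposure to tobacco (smoking) mutagens
Signature 6	Defective DNA mismatch repair
Signature 7	Ultraviolet light exposure
Signature 10	Altered activity of the error-prone polymerase POLE
Signature 13	Activity of the AID/APOBEC family of cytidine deaminases
Signature 14	Loss of mismatch repair and polymerase proofreading
Signature 20	Loss of mismatch repair and polymerase proofreading
Signature 26	Defective DNA mismatch repair
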