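>fan-miR156a family=miR156
UGACAGAAGAGAGUGAGCAC
>fan-miR159a family=miR159
UUUGGAUUGAAGGGAGCUCUA
>fan-miR164a family=miR164
UGGAGAAGCAGGGCACGUGCA
>fan-miR166a family=miR166
UCGGACCAGGCUUCAUUCCCC
>fan-miR172a family=miR172
AGAAUCUUGAUGAUGCUGCAU
>fan-miR390a family=miR390
AAGCUCAGGAGGGAUAGCGCC
>fan-miR395a family=miR395
CUGAAGUGUUUGGGGGAACUC
>fan-miR482a family=miR482
UCUUUCCUACUCCUCCCAUUCC
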