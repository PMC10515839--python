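((ABa,((((((((RIMLU))))))),(((((((RIMRU))))))),((((((((ASIL)))))),((((((ASIR)))))))),(((((((((ADLL))))))),(((((((ADLR))))))))),((((((((((ASKL)))))))),((((((((ASKR)))))))))),((((((((ADAL)))))),((((((ADAR)))))))),((((((((PHBL)))))),((((((PHBR)))))))),(((((((PVQL))))),(((((PVQR))))))),((((RICL)),((RICR)))))ABp)AB,P1)P0;
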