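<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="global" description="categorías compartidas por todos los contextos">
    <category>
      <pattern>GRACIAS</pattern>
      <template><random>
        <li>¡De nada! ¿De qué más te gustaría platicar?</li>
        <li>Con mucho gusto. ¿Seguimos platicando?</li>
      </random></template>
    </category>
    <category>
      <pattern>GRACIAS _</pattern>
      <template><srai>GRACIAS</srai></template>
    </category>
    <category>
      <pattern>MUCHAS GRACIAS</pattern>
      <template><srai>GRACIAS</srai></template>
    </category>
    <category>
      <pattern>ME GUSTA *</pattern>
      <template><random>
        <li>¡Qué bien! ¿Por qué te gusta tanto?</li>
        <li>¡Qué bonito! ¿Desde cuándo te gusta?</li>
      </random></template>
    </category>
    <category>
      <pattern>ME ENCANTA *</pattern>
      <template><random>
        <li>¡Se nota que lo disfrutas! ¿Qué es lo que más te gusta de eso?</li>
        <li>¡Qué gusto! ¿Me cuentas más?</li>
      </random></template>
    </category>
    <category>
      <pattern>NO SÉ</pattern>
      <template><random>
        <li>No te preocupes, no pasa nada. ¿Quieres que platiquemos de otra cosa?</li>
        <li>Está bien, tómate tu tiempo. ¿Qué te gustaría recordar?</li>
      </random></template>
    </category>
    <category>
      <pattern>NO ME ACUERDO</pattern>
      <template><random>
        <li>Está bien, no te preocupes. ¿Platicamos de otro tema?</li>
        <li>No pasa nada, los recuerdos llegan solitos. ¿Seguimos platicando?</li>
      </random></template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Me gusta escucharte. ¿Me cuentas un poco más?</li>
        <li>Entiendo. ¿Qué más me quieres contar?</li>
      </random></template>
    </category>
  </topic>
</aiml>
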